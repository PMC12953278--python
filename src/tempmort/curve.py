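"""Reduction of a fitted DLNM to the overall cumulative exposure-response
curve, relative-risk prediction centred at the minimum-mortality
temperature (MMT), and adaptation scaling of the heat side.

The overall cumulative curve sums the exposure-lag-response surface over
lags 0..max_lag; it is the curve conventionally reported for
temperature-mortality associations.  Risks are expressed relative to the
MMT, a fixed per-region reference temperature at which RR = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .basis import CrossBasisSpec, SplineSpec, ns_basis
from .dlnm import FittedDLNM


@dataclass
class AdaptationScenario:
    """Stipulated proportional reduction of heat-side excess relative risk.

    fraction = 0 means no adaptation; 0.2 and 0.5 are the moderate and
    strong scenarios; 1 removes the heat effect entirely.
    """

    fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"adaptation fraction must be in [0, 1], got {self.fraction}")


NO_ADAPTATION = AdaptationScenario(0.0)


@dataclass
class ReducedCurve:
    """Lag-summed (overall cumulative) exposure-response curve.

    ``coef``/``vcov`` live on the exposure-basis columns; predictions are
    centred at ``mmt`` by contrast, so log-RR(mmt) is exactly 0 with zero
    variance.
    """

    coef: np.ndarray
    vcov: np.ndarray
    spec: SplineSpec
    mmt: float

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.vcov.shape != (self.coef.size, self.coef.size):
            raise ValueError("vcov shape does not match coef")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")

    def centred_basis(self, temps) -> np.ndarray:
        """b(T) - b(mmt): the contrast matrix used for every prediction."""
        temps = np.atleast_1d(np.asarray(temps, dtype=float))
        b = ns_basis(temps, self.spec)
        b0 = ns_basis(np.array([self.mmt]), self.spec)
        return b - b0

    def log_rr(self, temps) -> np.ndarray:
        return self.centred_basis(temps) @ self.coef


def reduce_overall(fit: FittedDLNM, cbspec: CrossBasisSpec, mmt: float) -> ReducedCurve:
    """Sum the fitted surface over lags 0..max_lag.

    With cross-basis columns ordered exposure-major, the reduction matrix
    M is block diagonal: each exposure coefficient picks up the column sums
    of the lag basis over integer lags.  coef = M theta, vcov = M V M'.
    """
    if fit.cbspec is not None and fit.cbspec is not cbspec and fit.cbspec != cbspec:
        raise ValueError("cross-basis spec does not match the one used in the fit")
    theta, V = fit.crossbasis_block()
    vx, vl = cbspec.vx, cbspec.vl
    if theta.size != vx * vl:
        raise ValueError(
            f"label mismatch: fit carries {theta.size} cross-basis columns, spec implies {vx * vl}"
        )
    lag_sums = cbspec.lag_basis_matrix().sum(axis=0)  # length vl
    M = np.kron(np.eye(vx), lag_sums)  # vx x (vx*vl)
    return ReducedCurve(coef=M @ theta, vcov=M @ V @ M.T, spec=cbspec.var_spec, mmt=mmt)


def predict_rr(curve: ReducedCurve, temps, alpha: float = 0.05) -> pd.DataFrame:
    """Relative risk with Wald CIs on the log scale, centred at the MMT.

    Returns a frame with columns temperature, rr, lo95, hi95.  At the MMT
    the RR is exactly 1 with a degenerate [1, 1] interval.
    """
    temps = np.atleast_1d(np.asarray(temps, dtype=float))
    if temps.size == 0:
        raise ValueError("empty temperature grid")
    C = curve.centred_basis(temps)
    logrr = C @ curve.coef
    var = np.einsum("ij,jk,ik->i", C, curve.vcov, C)
    se = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return pd.DataFrame(
        {
            "temperature": temps,
            "rr": np.exp(logrr),
            "lo95": np.exp(logrr - z * se),
            "hi95": np.exp(logrr + z * se),
        }
    )


def apply_adaptation(rr_value, scenario: AdaptationScenario, is_heat) -> np.ndarray:
    """Scale heat-side excess relative risk: RR' = 1 + (1-a)(RR-1).

    Cold-side values pass through untouched.  The excess-risk scaling never
    drives a heat RR below 1 (full adaptation maps every heat RR to exactly
    1), and it is applied identically to point estimates and Monte-Carlo
    draws.
    """
    rr = np.asarray(rr_value, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risks must be positive")
    heat = np.asarray(is_heat, dtype=bool)
    out = np.where(heat, 1.0 + (1.0 - scenario.fraction) * (rr - 1.0), rr)
    return out if out.ndim else float(out)


def export_curve(curve: ReducedCurve, temps, path) -> None:
    """Write the curve as a delimited table (temperature, rr, lo95, hi95)."""
    predict_rr(curve, temps).to_csv(path, index=False)
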