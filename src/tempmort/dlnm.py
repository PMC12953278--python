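"""Quasi-Poisson DLNM fitting and qAIC-based knot selection.

The regression of daily death counts on the cross-basis follows the
canonical time-series design in environmental epidemiology:

    log E[Y_t] = alpha + crossbasis(T, lag) + ns(t; trend df) + day-of-week

with a quasi-Poisson family (Poisson likelihood, Pearson-estimated
overdispersion scaling the covariance).  Knot alternatives are compared by
the quasi-AIC, which inflates the parameter penalty by the estimated
dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import gammaln

from .basis import (
    CrossBasis,
    CrossBasisSpec,
    SplineSpec,
    build_crossbasis,
    exposure_spec_from_sample,
    lag_spec,
    ns_basis,
)
from .io import DailySeries

log = logging.getLogger(__name__)


@dataclass
class FittedDLNM:
    """Converged quasi-Poisson fit.

    ``covariance`` is already scaled by the Pearson dispersion estimate;
    ``loglik`` is the (unscaled) Poisson log-likelihood at the fit.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    loglik: float
    n_used: int
    design_labels: list[str]
    cbspec: CrossBasisSpec | None = None

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def crossbasis_block(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients and covariance restricted to cross-basis columns."""
        idx = [i for i, lab in enumerate(self.design_labels) if lab.startswith("cb_")]
        if not idx:
            raise ValueError("fit contains no cross-basis block")
        idx = np.asarray(idx)
        return self.coefficients[idx], self.covariance[np.ix_(idx, idx)]

    def summary_frame(self):
        import pandas as pd

        se = np.sqrt(np.diag(self.covariance))
        return pd.DataFrame({"term": self.design_labels, "estimate": self.coefficients, "std_error": se})


@dataclass
class KnotCandidate:
    """One knot alternative scored by qAIC."""

    var_knot_percentiles: tuple[float, ...]
    lag_internal_knots: int
    qaic: float = np.nan

    @property
    def total_df(self) -> int:
        # vx * vl of the implied cross-basis
        return (len(self.var_knot_percentiles) + 1) * (self.lag_internal_knots + 2)


#: Candidate grid scored when the qAIC variant is requested.  The first
#: entry is the fixed-knots default, which also serves as the tie-break
#: preference.
DEFAULT_CANDIDATES: tuple[KnotCandidate, ...] = tuple(
    KnotCandidate(var_knot_percentiles=vp, lag_internal_knots=lk)
    for vp in ((10, 75, 90), (10, 50, 90), (25, 50, 75), (33, 66), (50,))
    for lk in (1, 2, 3)
)

FIXED_KNOTS_DEFAULT = KnotCandidate(var_knot_percentiles=(10, 75, 90), lag_internal_knots=2)


def crossbasis_spec_for(series: DailySeries, candidate: KnotCandidate, max_lag: int = 21) -> CrossBasisSpec:
    """Materialise a candidate into a cross-basis spec with exposure knots
    at the stated percentiles of this region's fitting-period temperatures."""
    return CrossBasisSpec(
        var_spec=exposure_spec_from_sample(series.tmean, candidate.var_knot_percentiles),
        lag_spec=lag_spec(max_lag, candidate.lag_internal_knots),
        max_lag=max_lag,
    )


def trend_basis(n_days: int, trend_df_per_year: int) -> np.ndarray:
    """Natural cubic spline of the day index with round(df/year * years)
    degrees of freedom (no intercept column), controlling seasonality and
    the long-term trend."""
    years = n_days / 365.25
    df = int(round(trend_df_per_year * years))
    if df < 1:
        raise ValueError("trend spline needs at least 1 df; series too short")
    x = np.arange(n_days, dtype=float)
    # equally spaced interior knots on the (uniform) day index
    probs = np.linspace(0, 1, df + 1)[1:-1]
    internal = tuple(np.quantile(x, probs)) if df > 1 else ()
    spec = SplineSpec(internal_knots=internal, boundary_knots=(0.0, float(n_days - 1)), with_intercept=False)
    return ns_basis(x, spec)


def dow_indicators(dates) -> np.ndarray:
    """Six day-of-week indicator columns, Monday as the reference."""
    dow = np.asarray(dates.dayofweek)
    return np.column_stack([(dow == d).astype(float) for d in range(1, 7)])


def build_design(series: DailySeries, cb: CrossBasis, trend_df_per_year: int = 7):
    """Assemble the full design matrix, response and usable-row mask.

    Columns: intercept | cross-basis block | trend spline | 6 day-of-week
    indicators.  Rows with a missing death count or an incomplete lag
    window are masked out of the fit; their temperatures still feed the
    lag windows of later days (built into the cross-basis).
    """
    n = len(series)
    if cb.matrix.shape[0] != n:
        raise ValueError("series and cross-basis are not aligned")
    trend = trend_basis(n, trend_df_per_year)
    dow = dow_indicators(series.dates)
    design = np.column_stack([np.ones(n), cb.matrix, trend, dow])
    labels = (
        ["intercept"]
        + cb.labels
        + [f"trend_{i + 1}" for i in range(trend.shape[1])]
        + [f"dow_{d}" for d in ("tue", "wed", "thu", "fri", "sat", "sun")]
    )
    mask = np.isfinite(series.deaths)
    mask[: cb.valid_from] = False
    if not mask.any():
        raise ValueError("all rows masked: no usable days to fit")
    X = design[mask]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design: {_collinear_block(X, cb)}")
    return design, series.deaths, mask, labels


def _collinear_block(X: np.ndarray, cb: CrossBasis) -> str:
    ncb = cb.matrix.shape[1]
    blocks = {
        "cross-basis": slice(0, 1 + ncb),
        "trend": slice(0, X.shape[1] - 6),
        "day-of-week": slice(0, X.shape[1]),
    }
    prev_rank = 1
    prev_stop = 1
    for name, sl in blocks.items():
        sub = X[:, sl]
        r = np.linalg.matrix_rank(sub)
        if r < prev_rank + (sl.stop - prev_stop):
            return f"collinearity within the {name} block"
        prev_rank, prev_stop = r, sl.stop
    return "collinearity of unknown origin"


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood (with the y! term, scale 1)."""
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def fit_quasipoisson(design: np.ndarray, response: np.ndarray, mask=None, labels=None,
                     cbspec: CrossBasisSpec | None = None, maxiter: int = 100) -> FittedDLNM:
    """Fit the quasi-Poisson GLM by IRLS.

    Coefficients maximise the Poisson log-likelihood; the dispersion is the
    Pearson chi-square divided by the residual degrees of freedom, and the
    covariance is dispersion times the inverse Fisher information.
    """
    if mask is None:
        mask = np.ones(len(response), dtype=bool)
    X = design[mask]
    y = np.asarray(response, dtype=float)[mask]
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=1e-9, scale="X2")
    if not getattr(res, "converged", True):
        raise RuntimeError(f"IRLS did not converge in {maxiter} iterations (last deviance {res.deviance:.6g})")
    mu = res.fittedvalues
    n, p = X.shape
    dispersion = float(np.sum((y - mu) ** 2 / mu) / (n - p))
    return FittedDLNM(
        coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        dispersion=dispersion,
        loglik=poisson_loglik(y, mu),
        n_used=n,
        design_labels=list(labels) if labels is not None else [f"x{i}" for i in range(p)],
        cbspec=cbspec,
    )


def qaic(fit: FittedDLNM) -> float:
    """Quasi-AIC: -2*loglik + 2*p*dispersion.

    At dispersion 1 this reduces to the ordinary AIC; overdispersion
    inflates the parameter penalty.
    """
    return -2.0 * fit.loglik + 2.0 * fit.n_params * fit.dispersion


def fit_series(series: DailySeries, candidate: KnotCandidate = FIXED_KNOTS_DEFAULT,
               max_lag: int = 21, trend_df_per_year: int = 7) -> FittedDLNM:
    """Convenience wrapper: cross-basis, design and fit for one region."""
    spec = crossbasis_spec_for(series, candidate, max_lag)
    cb = build_crossbasis(series.tmean, spec)
    design, response, mask, labels = build_design(series, cb, trend_df_per_year)
    return fit_quasipoisson(design, response, mask, labels, cbspec=spec)


def select_spec(series: DailySeries, candidates=DEFAULT_CANDIDATES, max_lag: int = 21,
                trend_df_per_year: int = 7) -> KnotCandidate:
    """Score each knot candidate by qAIC and return the minimiser.

    Ties (to machine precision) break toward fewer total cross-basis df,
    then toward the fixed-knots default.  Candidates that fail to fit are
    skipped with a warning; if all fail, an error is raised.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates supplied")
    scored: list[KnotCandidate] = []
    for cand in candidates:
        try:
            fit = fit_series(series, cand, max_lag, trend_df_per_year)
        except Exception as exc:  # noqa: BLE001 - any fit failure skips the candidate
            log.warning("candidate %s failed to fit: %s", cand, exc)
            continue
        scored.append(
            KnotCandidate(
                var_knot_percentiles=tuple(cand.var_knot_percentiles),
                lag_internal_knots=cand.lag_internal_knots,
                qaic=qaic(fit),
            )
        )
    if not scored:
        raise RuntimeError("all knot candidates failed to fit")
    if len(scored) == 1:
        return scored[0]

    def is_default(c: KnotCandidate) -> bool:
        return (
            tuple(c.var_knot_percentiles) == FIXED_KNOTS_DEFAULT.var_knot_percentiles
            and c.lag_internal_knots == FIXED_KNOTS_DEFAULT.lag_internal_knots
        )

    best = min(scored, key=lambda c: (c.qaic, c.total_df, not is_default(c)))
    return best
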