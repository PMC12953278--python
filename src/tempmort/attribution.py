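"""Attributable deaths at non-optimal temperature.

For each day the attributable number (AN) is

    AN_t = D_t * (1 - exp(-logRR(T_t)))

with the log relative risk taken from the overall cumulative curve centred
at the minimum-mortality temperature.  Days warmer than the MMT contribute
to the heat component, colder days to cold.  Decade aggregates, the
attributable fraction (AF, % of total deaths), end-of-century/baseline
ratios and Monte-Carlo empirical confidence intervals follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve import NO_ADAPTATION, AdaptationScenario, ReducedCurve, apply_adaptation

log = logging.getLogger(__name__)

COMPONENTS = ("heat", "cold", "total")


@dataclass
class AttributionResult:
    """Per-decade attributable numbers/fractions with MC confidence bands.

    ``per_decade`` columns: decade, component, an, af, lo95, hi95.
    """

    per_decade: pd.DataFrame
    n_mc: int
    seed: int


def _adapted_log_rr(curve: ReducedCurve, tmean: np.ndarray, coef=None,
                    adaptation: AdaptationScenario = NO_ADAPTATION) -> np.ndarray:
    """Centred log-RR per day (optionally under alternative coefficients),
    with adaptation scaling applied to the heat side."""
    C = curve.centred_basis(tmean)
    logrr = C @ (curve.coef if coef is None else coef)
    heat = np.asarray(tmean, dtype=float) > curve.mmt
    if adaptation.fraction > 0:
        rr = apply_adaptation(np.exp(logrr), adaptation, is_heat=heat[..., None] if logrr.ndim > 1 else heat)
        logrr = np.log(rr)
    return logrr


def daily_attributable(deaths, tmean, curve: ReducedCurve,
                       adaptation: AdaptationScenario = NO_ADAPTATION):
    """Per-day attributable deaths and their heat/cold component label.

    Returns ``(an, component)`` where component is 'heat' for T > MMT,
    'cold' for T < MMT and 'none' exactly at the MMT (where AN = 0 by
    centring).  Negative AN is legal: it occurs wherever the fitted curve
    dips below RR = 1 on that side.
    """
    deaths = np.asarray(deaths, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    if np.any(deaths[np.isfinite(deaths)] < 0):
        raise ValueError("deaths must be non-negative")
    logrr = _adapted_log_rr(curve, tmean, adaptation=adaptation)
    an = deaths * (1.0 - np.exp(-logrr))
    component = np.where(tmean > curve.mmt, "heat", np.where(tmean < curve.mmt, "cold", "none"))
    return an, component


def _decade_mask(dates: pd.DatetimeIndex, decade) -> np.ndarray:
    a, b = decade
    return (dates.year >= a) & (dates.year <= b)


def aggregate_decades(dates: pd.DatetimeIndex, an: np.ndarray, component: np.ndarray,
                      deaths: np.ndarray, decades) -> pd.DataFrame:
    """Sum daily AN within closed calendar decades and express AF as a
    percentage of the total deaths over the same days."""
    dates = pd.DatetimeIndex(dates)
    deaths = np.asarray(deaths, dtype=float)
    rows = []
    for decade in decades:
        m = _decade_mask(dates, decade)
        total_deaths = np.nansum(deaths[m])
        if total_deaths <= 0:
            raise ValueError(f"decade {decade} has zero total deaths; AF undefined")
        for comp in COMPONENTS:
            cm = m if comp == "total" else (m & (component == comp))
            an_sum = float(np.nansum(an[cm]))
            rows.append(
                {
                    "decade": f"{decade[0]}-{decade[1]}",
                    "component": comp,
                    "an": an_sum,
                    "af": 100.0 * an_sum / total_deaths,
                }
            )
    return pd.DataFrame(rows)


def change_ratio(an_future: float, an_baseline: float) -> float:
    """Future/baseline AN ratio rounded half-away-from-zero to 1 decimal.

    A non-positive baseline makes the ratio undefined (returned as NaN,
    printed as '-' in tables), computed from unrounded inputs and rounded
    last.
    """
    if an_baseline <= 0:
        return float("nan")
    r = an_future / an_baseline
    return np.sign(r) * np.floor(abs(r) * 10 + 0.5) / 10


def sample_coefficients(curve: ReducedCurve, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate-normal draws of the reduced-curve coefficients.

    Cholesky when the covariance permits; otherwise an eigenvalue square
    root with negative eigenvalues clipped at zero (logged).
    """
    k = curve.coef.size
    try:
        L = np.linalg.cholesky(curve.vcov) if np.any(curve.vcov) else np.zeros((k, k))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(curve.vcov)
        if np.any(w < 0):
            log.info("vcov not PSD to machine precision; clipping %d negative eigenvalue(s)", int(np.sum(w < 0)))
        L = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n_draws, k))
    return curve.coef + z @ L.T


def montecarlo_ci(curve: ReducedCurve, deaths, tmean, dates, decades,
                  adaptation: AdaptationScenario = NO_ADAPTATION,
                  n_draws: int = 1000, seed: int = 0) -> AttributionResult:
    """Empirical 95% confidence intervals for decade AN/AF by Monte Carlo.

    Coefficients are drawn once from their sampling distribution and shared
    across decades, so draws are coherent in time; percentiles (2.5/97.5,
    linear interpolation) are taken per decade and component.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(dates)
    deaths = np.asarray(deaths, dtype=float)
    tmean = np.asarray(tmean, dtype=float)

    an, component = daily_attributable(deaths, tmean, curve, adaptation)
    point = aggregate_decades(dates, an, component, deaths, decades)

    draws = sample_coefficients(curve, n_draws, rng)  # (n_draws, vx)
    C = curve.centred_basis(tmean)  # (n_days, vx)
    logrr = C @ draws.T  # (n_days, n_draws)
    if adaptation.fraction > 0:
        heat = tmean > curve.mmt
        rr = apply_adaptation(np.exp(logrr), adaptation, is_heat=heat[:, None])
        logrr = np.log(rr)
    an_draws = deaths[:, None] * (1.0 - np.exp(-logrr))

    lo, hi = [], []
    for decade in decades:
        m = _decade_mask(dates, decade)
        total_deaths = np.nansum(deaths[m])
        for comp in COMPONENTS:
            cm = m if comp == "total" else (m & (component == comp))
            sums = np.nansum(an_draws[cm], axis=0)
            qs = np.percentile(sums, [2.5, 97.5])
            lo.append(qs[0])
            hi.append(qs[1])
    out = point.copy()
    out["lo95"] = lo
    out["hi95"] = hi
    return AttributionResult(per_decade=out, n_mc=n_draws, seed=seed)
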