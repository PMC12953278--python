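"""Future projections: baseline death series, population scaling, climate
ensembles, and the orchestration of attribution per scenario.

Future daily baseline deaths are the day-of-year climatology of observed
deaths scaled by a population factor (death rates held at their reference
proportion of the population, with no life-expectancy trend).  The
attributable-number machinery is applied to each climate-ensemble member;
point estimates average across members and confidence intervals pool the
coefficient Monte-Carlo draws across members, so they reflect both
coefficient and climate-model spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import (
    COMPONENTS,
    AttributionResult,
    _decade_mask,
    aggregate_decades,
    daily_attributable,
    sample_coefficients,
)
from .curve import NO_ADAPTATION, AdaptationScenario, ReducedCurve, apply_adaptation
from .io import DailySeries

log = logging.getLogger(__name__)


@dataclass
class ClimateEnsemble:
    """Daily temperature series from one or more climate models under a
    single emission scenario, sharing the same date axis."""

    scenario_id: str
    dates: pd.DatetimeIndex
    members: dict[str, np.ndarray]  # model_id -> tmean

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        for mid, t in self.members.items():
            t = np.asarray(t, dtype=float)
            if t.size != len(self.dates):
                raise ValueError(f"member {mid} does not share the ensemble date axis")
            self.members[mid] = t


@dataclass
class PopulationTrajectory:
    """Population at 5-year anchor years, linearly interpolated between."""

    anchor_years: np.ndarray
    population: np.ndarray
    baseline_year: int
    enabled: bool = True

    def __post_init__(self) -> None:
        self.anchor_years = np.asarray(self.anchor_years, dtype=int)
        self.population = np.asarray(self.population, dtype=float)
        if self.anchor_years.size != self.population.size:
            raise ValueError("anchor_years and population must align")
        if np.any(self.population <= 0):
            raise ValueError("population must be positive at every anchor")
        if np.any(np.diff(self.anchor_years) <= 0):
            raise ValueError("anchor years must be strictly increasing")


DISABLED_POPULATION = PopulationTrajectory(
    anchor_years=np.array([2010, 2100]), population=np.array([1.0, 1.0]), baseline_year=2010, enabled=False
)


def baseline_death_series(series: DailySeries) -> dict[tuple[int, int], float]:
    """Day-of-year climatology of observed deaths.

    Returns a (month, day) -> mean deaths/day mapping over 366 calendar
    days; Feb 29 is imputed as the Feb 28 / Mar 1 average when unobserved
    days leave it short.  Missing (suppressed) days are excluded from each
    mean.
    """
    if len(series) < 2 * 365:
        raise ValueError("need at least two full years of observed deaths")
    df = pd.DataFrame({"month": series.dates.month, "day": series.dates.day, "deaths": series.deaths})
    clim = df.groupby(["month", "day"])["deaths"].mean()
    out = {}
    for (m, d), v in clim.items():
        if np.isnan(v) and (m, d) != (2, 29):
            raise ValueError(f"calendar day {m:02d}-{d:02d} has no non-missing observations")
        out[(int(m), int(d))] = float(v)
    feb29 = out.get((2, 29), np.nan)
    if not np.isfinite(feb29):
        out[(2, 29)] = 0.5 * (out[(2, 28)] + out[(3, 1)])
    return out


def climatology_series(climatology: dict[tuple[int, int], float], dates: pd.DatetimeIndex) -> np.ndarray:
    """Expand a day-of-year climatology onto an arbitrary date axis."""
    return np.array([climatology[(m, d)] for m, d in zip(dates.month, dates.day)])


def population_factor(traj: PopulationTrajectory, year) -> np.ndarray:
    """Population multiplier relative to the baseline year, linearly
    interpolated between 5-year anchors.  A disabled trajectory returns 1."""
    year = np.atleast_1d(np.asarray(year, dtype=float))
    if not traj.enabled:
        out = np.ones_like(year)
        return out if out.size > 1 else float(out[0])
    lo, hi = traj.anchor_years[0], traj.anchor_years[-1]
    if np.any(year < traj.baseline_year) or np.any(year < lo) or np.any(year > hi):
        raise ValueError(f"year outside [{max(lo, traj.baseline_year)}, {hi}]")
    base = np.interp(traj.baseline_year, traj.anchor_years, traj.population)
    out = np.interp(year, traj.anchor_years, traj.population) / base
    return out if out.size > 1 else float(out[0])


def project_scenario(curve: ReducedCurve, ensemble: ClimateEnsemble,
                     climatology: dict[tuple[int, int], float],
                     traj: PopulationTrajectory = DISABLED_POPULATION,
                     adaptation: AdaptationScenario = NO_ADAPTATION,
                     decades=(), n_draws: int = 1000, seed: int = 0) -> AttributionResult:
    """Decade attributable numbers under one climate scenario.

    Per member: future baseline deaths D_t = climatology(day-of-year) x
    population factor(year); daily attribution with the adapted curve on
    member temperatures; decade sums.  The point estimate is the ensemble
    mean; the 95% band is the empirical 2.5/97.5 percentile of the MC draws
    pooled across members.
    """
    dates = ensemble.dates
    years = np.asarray(dates.year)
    for a, b in decades:
        if years.min() > a or years.max() < b:
            raise ValueError(f"ensemble dates do not cover decade ({a}, {b})")
    deaths = climatology_series(climatology, dates) * np.asarray(population_factor(traj, years))

    members = {}
    for mid, tmean in ensemble.members.items():
        covered = all(np.all(np.isfinite(tmean[_decade_mask(dates, d)])) for d in decades)
        if covered:
            members[mid] = tmean
        else:
            log.warning("member %s dropped: incomplete temperature coverage of a decade", mid)
    if not members:
        raise ValueError("every ensemble member lacks coverage of some decade")

    rng = np.random.default_rng(seed)
    per_member = []
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for mid, tmean in members.items():
        an, component = daily_attributable(deaths, tmean, curve, adaptation)
        per_member.append(aggregate_decades(dates, an, component, deaths, decades).assign(member=mid))

        draws = sample_coefficients(curve, n_draws, rng)
        C = curve.centred_basis(tmean)
        logrr = C @ draws.T
        if adaptation.fraction > 0:
            rr = apply_adaptation(np.exp(logrr), adaptation, is_heat=(tmean > curve.mmt)[:, None])
            logrr = np.log(rr)
        an_draws = deaths[:, None] * (1.0 - np.exp(-logrr))
        for decade in decades:
            m = _decade_mask(dates, decade)
            for comp in COMPONENTS:
                cm = m if comp == "total" else (m & (component == comp))
                key = (f"{decade[0]}-{decade[1]}", comp)
                pooled.setdefault(key, []).append(np.nansum(an_draws[cm], axis=0))

    stacked = pd.concat(per_member, ignore_index=True)
    point = stacked.groupby(["decade", "component"], sort=False)[["an", "af"]].mean().reset_index()
    lo, hi = [], []
    for _, row in point.iterrows():
        sums = np.concatenate(pooled[(row["decade"], row["component"])])
        qs = np.percentile(sums, [2.5, 97.5])
        lo.append(qs[0])
        hi.append(qs[1])
    point["lo95"] = lo
    point["hi95"] = hi
    return AttributionResult(per_decade=point, n_mc=n_draws * len(members), seed=seed)


def run_full_pipeline(config, study, out_dir=None,
                      adaptations=(0.0,), population_on: bool = False) -> dict:
    """Fit, reduce, attribute and project every included region of a study.

    ``study`` is a SyntheticStudy (or any object exposing the same fields:
    series per region, registry, ensembles per scenario, population
    trajectory).  Returns a nested results bundle; if ``out_dir`` is given,
    curve exports and result tables are also written there as delimited
    text.  Deterministic given ``config.seed``.
    """
    from pathlib import Path

    from . import dlnm
    from .attribution import change_ratio
    from .curve import AdaptationScenario, export_curve, reduce_overall

    results: dict = {}
    registry = study.registry
    for rid, series in study.series.items():
        reg = registry[rid]
        if not reg.included:
            log.info("skipping excluded region %s (missing fraction %.2f)", rid, reg.missing_fraction)
            continue
        if config.model_variant == "qaic_knots":
            candidate = dlnm.select_spec(series, max_lag=config.max_lag,
                                         trend_df_per_year=config.trend_df_per_year)
        else:
            candidate = dlnm.FIXED_KNOTS_DEFAULT
        fit = dlnm.fit_series(series, candidate, config.max_lag, config.trend_df_per_year)
        curve = reduce_overall(fit, fit.cbspec, mmt=reg.mmt)
        climatology = baseline_death_series(series)
        region_res: dict = {"fit": fit, "curve": curve, "candidate": candidate, "scenarios": {}}
        for scen_id, ensemble in study.ensembles.items():
            traj = study.population if population_on else DISABLED_POPULATION
            for a in adaptations:
                res = project_scenario(
                    curve, ensemble, climatology, traj=traj,
                    adaptation=AdaptationScenario(a), decades=config.decades,
                    n_draws=config.mc_draws, seed=config.seed,
                )
                tab = res.per_decade.copy()
                heat = tab[tab.component == "heat"].set_index("decade")
                first, last = tab.decade.iloc[0], tab.decade.iloc[-1]
                ratio = change_ratio(heat.loc[last, "an"], heat.loc[first, "an"])
                region_res["scenarios"][(scen_id, a)] = {"result": res, "heat_ratio": ratio}
        results[rid] = region_res

        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            grid = np.linspace(series.tmean.min(), series.tmean.max(), 101)
            export_curve(curve, grid, out / f"curve_{rid}.csv")
            fit.summary_frame().to_csv(out / f"fit_{rid}.csv", index=False)
            for (scen_id, a), payload in region_res["scenarios"].items():
                tab = payload["result"].per_decade.assign(
                    region=rid, scenario=scen_id, adaptation=a, heat_ratio=payload["heat_ratio"]
                )
                tab.to_csv(out / f"attribution_{rid}_{scen_id}_a{int(a * 100)}.csv", index=False)
    return results
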