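"""Synthetic study generator.

Fabricates every input the pipeline needs with the statistical structure
the analysis assumes: seasonal Finnish-like temperatures with AR(1) noise,
overdispersed daily death counts driven by a known V-shaped
exposure-lag-response surface plus smooth trend and day-of-week effects,
data-protection censoring of counts below three, pseudo-GCM warming
trajectories to 2100, and a 5-year-step population path.  Every generator
is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DailySeries
from .regions import RegionRegistry
from .scenarios import ClimateEnsemble, PopulationTrajectory

MAX_LAG = 21
#: burn-in prepended so the analysis window starts with full lag history
BURN_IN_DAYS = MAX_LAG + 1

# day-of-year of the warmest day; late July in Finland
_SEASON_PEAK_DOY = 205.0


def _front_loaded_profile(max_lag: int = MAX_LAG, decay: float = 0.5) -> np.ndarray:
    """Heat lag weights: geometric decay, most of the effect within days."""
    w = decay ** np.arange(max_lag + 1)
    return w / w.sum()


def _slow_decay_profile(max_lag: int = MAX_LAG, decay: float = 0.85) -> np.ndarray:
    """Cold lag weights: slow geometric decay over the full three weeks."""
    w = decay ** np.arange(max_lag + 1)
    return w / w.sum()


def harvesting_profile(max_lag: int = MAX_LAG, decay: float = 0.45, rebound: float = 0.03) -> np.ndarray:
    """Heat profile with a negative late tail (mortality displacement):
    deaths advanced by heat are partly removed from later weeks.  Weights
    still sum to 1 so cumulative risk is unchanged."""
    w = decay ** np.arange(max_lag + 1)
    w[10:] -= rebound
    return w / w.sum()


@dataclass
class TrueSurface:
    """Known exposure-lag-response surface used to drive the generator.

    Slopes are cumulative log-RR per degree away from the MMT; the lag
    profiles distribute that total over lags 0..21 and each sums to 1, so
    the overall cumulative curve of the generated data is exactly the
    V shape with these slopes.
    """

    mmt: float = 16.0
    cold_slope: float = float(np.log(1.4) / 20.0)
    heat_slope: float = float(np.log(1.3) / 10.0)
    cold_lag_decay: np.ndarray = field(default_factory=_slow_decay_profile)
    heat_lag_profile: np.ndarray = field(default_factory=_front_loaded_profile)

    def __post_init__(self) -> None:
        for name in ("cold_lag_decay", "heat_lag_profile"):
            w = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError(f"{name} must sum to 1")
            setattr(self, name, w)
        if self.cold_slope < 0 or self.heat_slope < 0:
            raise ValueError("slopes must be >= 0")

    def cumulative_log_rr(self, temps) -> np.ndarray:
        """True overall cumulative log-RR at given temperatures."""
        t = np.asarray(temps, dtype=float)
        return self.heat_slope * np.clip(t - self.mmt, 0, None) + self.cold_slope * np.clip(self.mmt - t, 0, None)


@dataclass
class ClimateGenSpec:
    """Seasonal-cycle-plus-AR(1) daily mean temperature generator.

    Defaults emulate southern Finland: annual mean 5 °C with a 13 °C
    seasonal amplitude peaking in late July, and autocorrelated synoptic
    noise.
    """

    annual_mean: float = 5.0
    seasonal_amplitude: float = 13.0
    ar1_coef: float = 0.7
    noise_sd: float = 2.0
    warming_by_2100: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.ar1_coef) < 1:
            raise ValueError("|ar1_coef| must be < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def gen_climate(spec: ClimateGenSpec, start: str, end: str,
                ramp_start_year: int | None = None, ramp_end_year: int = 2100) -> pd.Series:
    """Daily mean temperatures from start to end (inclusive).

    tmean_t = annual_mean + amplitude*cos(2*pi*(doy - peak)/365.25) + AR(1)
    noise, plus (when warming_by_2100 is non-zero) a linear warming ramp
    from 0 at ``ramp_start_year`` to ``warming_by_2100`` at 2100.
    Deterministic per seed.
    """
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = spec.annual_mean + spec.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.25
    )
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=len(dates))
    noise = np.empty(len(dates))
    # stationary start
    noise[0] = eps[0] / np.sqrt(1 - spec.ar1_coef**2)
    for i in range(1, len(dates)):
        noise[i] = spec.ar1_coef * noise[i - 1] + eps[i]
    t = seasonal + noise
    if spec.warming_by_2100:
        y0 = ramp_start_year if ramp_start_year is not None else dates[0].year
        frac_year = dates.year + (doy - 1) / 365.25
        ramp = np.clip((frac_year - y0) / (ramp_end_year - y0), 0, None)
        t = t + spec.warming_by_2100 * ramp
    return pd.Series(t, index=dates, name="tmean")


def gen_projection_members(warmings, scenario_id: str, start: str, end: str,
                           base_spec: ClimateGenSpec | None = None,
                           ramp_start_year: int = 2015, seed: int = 0) -> ClimateEnsemble:
    """Pseudo-GCM ensemble: one member per warming level, each a seasonal
    series plus a linear ramp reaching its warming_by_2100 at 2100."""
    if not len(warmings):
        raise ValueError("need at least one member")
    base = base_spec or ClimateGenSpec()
    members = {}
    for i, w in enumerate(warmings):
        spec = ClimateGenSpec(
            annual_mean=base.annual_mean,
            seasonal_amplitude=base.seasonal_amplitude,
            ar1_coef=base.ar1_coef,
            noise_sd=base.noise_sd,
            warming_by_2100=float(w),
            seed=seed + 1000 * (i + 1),
        )
        series = gen_climate(spec, start, end, ramp_start_year=ramp_start_year)
        members[f"gcm{i + 1}"] = series.to_numpy()
        dates = series.index
    return ClimateEnsemble(scenario_id=scenario_id, dates=dates, members=members)


#: end-of-century warming ranges (deg C vs the recent baseline) spanned by
#: the five pseudo-GCM members per emission scenario
SCENARIO_WARMING = {
    "SSP2-4.5": np.linspace(2.2, 5.5, 5),
    "SSP5-8.5": np.linspace(5.8, 9.1, 5),
}


def gen_mortality(tmean: pd.Series, surface: TrueSurface, baseline_rate: float = 15.0,
                  trend_amplitude: float = 0.05, dow_effects=None,
                  overdispersion: float = 1.5, seed: int = 0) -> np.ndarray:
    """Daily death counts from the known surface.

    log mu_t = log(baseline_rate) + smooth secular trend + day-of-week
    effect + sum_l w_l * g(T_{t-l}), with g the V-shaped cumulative log-RR
    split into cold and heat parts with their own lag profiles.  Counts are
    negative-binomial with variance = overdispersion * mu (Poisson when the
    multiplier is 1).  The first 21 days use only the lags available inside
    the series.
    """
    if overdispersion < 1:
        raise ValueError("overdispersion must be >= 1")
    t = np.asarray(tmean, dtype=float)
    if t.size < MAX_LAG + 1:
        raise ValueError(f"series must be longer than {MAX_LAG} days")
    dates = tmean.index
    n = t.size

    cold = surface.cold_slope * np.clip(surface.mmt - t, 0, None)
    heat = surface.heat_slope * np.clip(t - surface.mmt, 0, None)
    # distributed lag contribution: convolution with the lag profiles
    pad = np.zeros(MAX_LAG)
    lag_term = (
        np.convolve(np.concatenate([pad, cold]), surface.cold_lag_decay, mode="full")[MAX_LAG : MAX_LAG + n]
        + np.convolve(np.concatenate([pad, heat]), surface.heat_lag_profile, mode="full")[MAX_LAG : MAX_LAG + n]
    )

    x = np.arange(n, dtype=float)
    trend = trend_amplitude * np.sin(2 * np.pi * x / (n - 1 if n > 1 else 1))
    dow = np.zeros(7) if dow_effects is None else np.asarray(dow_effects, dtype=float)
    if dow.size != 7:
        raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
    dow_term = dow[dates.dayofweek]

    mu = np.exp(np.log(baseline_rate) + trend + dow_term + lag_term)
    rng = np.random.default_rng(seed)
    if overdispersion == 1.0:
        return rng.poisson(mu).astype(float)
    # NB2 with variance = phi * mu  =>  size r = mu / (phi - 1)
    r = mu / (overdispersion - 1.0)
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def censor_counts(deaths, threshold: int = 3) -> np.ndarray:
    """Data-protection suppression: counts below the threshold become
    missing (NaN).  threshold 0 is the identity."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    d = np.asarray(deaths, dtype=float).copy()
    d[d < threshold] = np.nan
    return d


def gen_population(start_pop: float, end_pop: float, start_year: int = 2010,
                   end_year: int = 2100, baseline_year: int = 2010) -> PopulationTrajectory:
    """Population path with 5-year anchors linearly interpolated between
    the two endpoints."""
    if start_pop <= 0 or end_pop <= 0:
        raise ValueError("populations must be positive")
    years = np.arange(start_year, end_year + 1, 5)
    pop = np.interp(years, [start_year, end_year], [start_pop, end_pop])
    return PopulationTrajectory(anchor_years=years, population=pop, baseline_year=baseline_year)


@dataclass
class SyntheticStudy:
    """Bundle of everything the pipeline consumes."""

    series: dict[str, DailySeries]
    registry: dict[str, RegionRegistry]
    ensembles: dict[str, ClimateEnsemble]
    population: PopulationTrajectory
    surfaces: dict[str, TrueSurface]


def make_region_series(region_id: str, surface: TrueSurface, start: str = "2000-01-01",
                       end: str = "2017-12-31", baseline_rate: float = 15.0,
                       overdispersion: float = 1.5, censor_threshold: int = 3,
                       climate_spec: ClimateGenSpec | None = None,
                       dow_effects=None, seed: int = 0) -> DailySeries:
    """One region's observed series, with a 22-day burn-in prepended so the
    requested window has complete lag history, and counts censored below
    the data-protection threshold."""
    burn_start = pd.Timestamp(start) - pd.Timedelta(days=BURN_IN_DAYS)
    spec = climate_spec or ClimateGenSpec(seed=seed)
    tm = gen_climate(spec, str(burn_start.date()), end)
    deaths = gen_mortality(tm, surface, baseline_rate=baseline_rate,
                           dow_effects=dow_effects, overdispersion=overdispersion, seed=seed + 7)
    deaths = censor_counts(deaths, censor_threshold)
    return DailySeries(region_id=region_id, dates=tm.index, deaths=deaths, tmean=tm.to_numpy())


def make_study(n_regions: int = 2, start: str = "2000-01-01", end: str = "2017-12-31",
               baseline_rate: float = 15.0, overdispersion: float = 1.5,
               n_members: int = 5, proj_end: str = "2099-12-31", seed: int = 0,
               low_population_regions: int = 0, censor_threshold: int = 3) -> SyntheticStudy:
    """Fabricate a full multi-region, two-scenario, n-member study.

    ``low_population_regions`` extra regions are generated at a rate of two
    deaths/day so their censored missing fraction exceeds one half,
    exercising the exclusion rule the way the four lowest-population real
    counties do.
    """
    series, registry, surfaces = {}, {}, {}
    specs = []
    for i in range(n_regions):
        rid = f"region{i + 1}"
        specs.append((rid, baseline_rate))
    for i in range(low_population_regions):
        specs.append((f"small{i + 1}", 2.0))

    for j, (rid, rate) in enumerate(specs):
        surface = TrueSurface()
        s = make_region_series(rid, surface, start, end, baseline_rate=rate,
                               overdispersion=overdispersion,
                               censor_threshold=censor_threshold, seed=seed + 101 * j)
        series[rid] = s
        surfaces[rid] = surface
        registry[rid] = RegionRegistry(region_id=rid, mmt=surface.mmt,
                                       missing_fraction=s.missing_fraction)

    from .io import apply_inclusion_rule

    registry = apply_inclusion_rule(registry)

    ensembles = {
        scen: gen_projection_members(np.linspace(w[0], w[-1], n_members), scen,
                                     "2010-01-01", proj_end, seed=seed + 77 * (k + 1))
        for k, (scen, w) in enumerate(SCENARIO_WARMING.items())
    }
    population = gen_population(5.4e6, 6.8e6)
    return SyntheticStudy(series=series, registry=registry, ensembles=ensembles,
                          population=population, surfaces=surfaces)
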