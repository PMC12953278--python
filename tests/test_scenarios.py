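import numpy as np
import pandas as pd
import pytest

from tempmort.curve import AdaptationScenario
from tempmort.io import DailySeries
from tempmort.scenarios import (
    DISABLED_POPULATION,
    ClimateEnsemble,
    PopulationTrajectory,
    baseline_death_series,
    climatology_series,
    population_factor,
    project_scenario,
)
from tempmort.synthetic import ClimateGenSpec, gen_climate, gen_population

from test_attribution import linear_curve


def constant_series(value=10.0, start="2000-01-01", end="2003-12-31"):
    dates = pd.date_range(start, end)
    return DailySeries("c", dates, np.full(len(dates), value), np.full(len(dates), 5.0))


class TestClimatology:
    def test_constant_input(self):
        clim = baseline_death_series(constant_series(10.0))
        assert len(clim) == 366
        assert all(v == pytest.approx(10.0) for v in clim.values())

    def test_mean_of_years(self):
        dates = pd.date_range("2001-01-01", "2002-12-31")  # no leap day observed
        deaths = np.where(dates.year == 2001, 8.0, 12.0)
        s = DailySeries("m", dates, deaths, np.full(len(dates), 5.0))
        clim = baseline_death_series(s)
        assert clim[(1, 1)] == pytest.approx(10.0)
        # Feb 29 imputed as the Feb 28 / Mar 1 average
        assert clim[(2, 29)] == pytest.approx(0.5 * (clim[(2, 28)] + clim[(3, 1)]))

    def test_nonleap_year_total_matches_brute_force(self):
        s = constant_series(7.0)
        clim = baseline_death_series(s)
        dates = pd.date_range("2021-01-01", "2021-12-31")  # non-leap
        series = climatology_series(clim, dates)
        brute = sum(clim[(d.month, d.day)] for d in dates)
        assert series.sum() == pytest.approx(brute)
        assert series.sum() == pytest.approx(7.0 * 365)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="two full years"):
            baseline_death_series(constant_series(10.0, end="2000-12-31"))

    def test_missing_days_excluded_from_mean(self):
        s = constant_series(10.0)
        deaths = s.deaths.copy()
        # suppress Jan 1 in all but one year, leaving a single observed value
        jan1 = (s.dates.month == 1) & (s.dates.day == 1)
        idx = np.where(jan1)[0]
        deaths[idx[1:]] = np.nan
        deaths[idx[0]] = 4.0
        s2 = DailySeries("m", s.dates, deaths, s.tmean)
        clim = baseline_death_series(s2)
        assert clim[(1, 1)] == pytest.approx(4.0)


class TestPopulationFactor:
    def test_baseline_year_is_one(self):
        traj = gen_population(5.4e6, 6.8e6)
        assert population_factor(traj, 2010) == pytest.approx(1.0)

    def test_finland_ssp2_endpoint(self):
        """5.4M (2010) -> 6.8M (2100) gives factor 1.259 at 2100."""
        traj = gen_population(5.4e6, 6.8e6)
        assert population_factor(traj, 2100) == pytest.approx(1.259, abs=5e-4)

    def test_interpolation_between_anchors(self):
        traj = PopulationTrajectory(np.array([2010, 2015]), np.array([100.0, 110.0]), 2010)
        assert population_factor(traj, 2012) == pytest.approx(1.04)

    def test_outside_anchor_range_rejected(self):
        traj = gen_population(5.4e6, 6.8e6)
        with pytest.raises(ValueError):
            population_factor(traj, 2105)

    def test_disabled_trajectory_is_unity(self):
        assert population_factor(DISABLED_POPULATION, 2300) == pytest.approx(1.0)


def quiet_ensemble(n_members=1, warming=0.0, seed=0, end="2039-12-31"):
    """Low-noise ensemble so decade statistics are nearly deterministic."""
    members = {}
    for i in range(n_members):
        spec = ClimateGenSpec(ar1_coef=0.0, noise_sd=0.3, warming_by_2100=warming, seed=seed)
        t = gen_climate(spec, "2010-01-01", end, ramp_start_year=2015)
        members[f"m{i+1}"] = t.to_numpy()
        dates = t.index
    return ClimateEnsemble("test", dates, members)


@pytest.fixture
def flat_climatology():
    return {(m, d): 10.0 for m in range(1, 13) for d in range(1, 32)}


DECADES3 = [(2010, 2019), (2020, 2029), (2030, 2039)]


class TestProjectScenario:
    def test_stationary_single_member_keeps_baseline_an(self, flat_climatology):
        """Zero warming, no population growth, no adaptation: every future
        decade's AN stays at the baseline decade's level (within the
        generator's weather noise)."""
        curve = linear_curve(0.03, var=0.0)
        res = project_scenario(curve, quiet_ensemble(), flat_climatology,
                               decades=DECADES3, n_draws=100, seed=0)
        heat = res.per_decade[res.per_decade.component == "heat"]["an"].to_numpy()
        np.testing.assert_allclose(heat[1:], heat[0], rtol=0.05)

    def test_full_adaptation_zeroes_heat_only(self, flat_climatology):
        curve = linear_curve(0.03, var=0.0)
        res0 = project_scenario(curve, quiet_ensemble(), flat_climatology,
                                adaptation=AdaptationScenario(0.0),
                                decades=DECADES3, n_draws=100, seed=0)
        res1 = project_scenario(curve, quiet_ensemble(), flat_climatology,
                                adaptation=AdaptationScenario(1.0),
                                decades=DECADES3, n_draws=100, seed=0)
        t0 = res0.per_decade.set_index(["decade", "component"])
        t1 = res1.per_decade.set_index(["decade", "component"])
        assert (t1.xs("heat", level="component")["an"] == 0).all()
        pd.testing.assert_series_equal(
            t1.xs("cold", level="component")["an"], t0.xs("cold", level="component")["an"]
        )

    def test_population_doubling_doubles_an_af_invariant(self, flat_climatology):
        """AN is exactly linear in a constant population factor; AF is
        invariant to it."""
        curve = linear_curve(0.03, var=0.0)
        anchors = np.arange(2005, 2101, 5)
        pop = np.where(anchors >= 2010, 200.0, 100.0)
        doubling = PopulationTrajectory(anchors, pop, baseline_year=2005)
        res1 = project_scenario(curve, quiet_ensemble(), flat_climatology,
                                decades=DECADES3, n_draws=100, seed=0)
        res2 = project_scenario(curve, quiet_ensemble(), flat_climatology, traj=doubling,
                                decades=DECADES3, n_draws=100, seed=0)
        np.testing.assert_allclose(res2.per_decade["an"], 2 * res1.per_decade["an"], rtol=1e-12)
        np.testing.assert_allclose(res2.per_decade["af"], res1.per_decade["af"], rtol=1e-12)

    def test_ensemble_of_identical_members_collapses(self, flat_climatology):
        curve = linear_curve(0.03, var=1e-6)
        one = project_scenario(curve, quiet_ensemble(1), flat_climatology,
                               decades=DECADES3, n_draws=200, seed=0)
        three = project_scenario(curve, quiet_ensemble(3), flat_climatology,
                                 decades=DECADES3, n_draws=200, seed=0)
        np.testing.assert_allclose(three.per_decade["an"], one.per_decade["an"], rtol=1e-12)

    def test_uniform_warming_does_not_decrease_heat_an(self, flat_climatology):
        """+delta on all member temperatures cannot reduce decade heat AN
        when the heat side of the curve is non-decreasing."""
        curve = linear_curve(0.03, var=0.0)
        ens = quiet_ensemble()
        warmer = ClimateEnsemble("w", ens.dates, {k: v + 2.0 for k, v in ens.members.items()})
        r0 = project_scenario(curve, ens, flat_climatology, decades=DECADES3, n_draws=100, seed=0)
        r1 = project_scenario(curve, warmer, flat_climatology, decades=DECADES3, n_draws=100, seed=0)
        h0 = r0.per_decade[r0.per_decade.component == "heat"]["an"].to_numpy()
        h1 = r1.per_decade[r1.per_decade.component == "heat"]["an"].to_numpy()
        assert np.all(h1 >= h0 - 1e-9)

    def test_member_without_decade_coverage_dropped(self, flat_climatology):
        curve = linear_curve(0.03, var=0.0)
        ens = quiet_ensemble(2)
        broken = dict(ens.members)
        broken["m2"] = broken["m2"].copy()
        broken["m2"][-400:] = np.nan  # loses the 2030s
        ens_broken = ClimateEnsemble("b", ens.dates, broken)
        res = project_scenario(curve, ens_broken, flat_climatology,
                               decades=DECADES3, n_draws=100, seed=0)
        ref = project_scenario(curve, quiet_ensemble(1), flat_climatology,
                               decades=DECADES3, n_draws=100, seed=0)
        np.testing.assert_allclose(res.per_decade["an"], ref.per_decade["an"], rtol=1e-12)

    def test_decade_not_covered_rejected(self, flat_climatology):
        curve = linear_curve(0.03, var=0.0)
        with pytest.raises(ValueError, match="cover"):
            project_scenario(curve, quiet_ensemble(), flat_climatology,
                             decades=[(2010, 2019), (2090, 2099)], n_draws=100, seed=0)
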