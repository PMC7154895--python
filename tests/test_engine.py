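import dataclasses

import numpy as np
import pytest

from loliumsim.climate import ClimatologyConfig, ScenarioConfig
from loliumsim.engine import (
    SimulationConfig,
    annual_sb_map,
    cycle_growth_factor,
    deterministic_equilibrium,
    deterministic_fractions,
    low_density_growth_factor,
    percent_reduction,
    run_replicate,
    run_simulation,
)
from loliumsim.management import YearActions, actions_for_year

THIRDS = (1 / 3, 1 / 3, 1 / 3)
NO_ACTION = YearActions(("none", "none", "none"), None)


def config(pop, strategy, **kwargs):
    return SimulationConfig(population=pop, strategy=strategy, **kwargs)


class TestGrowthFactor:
    def test_uncontrolled_susceptible_value(self, susceptible_means):
        lam = low_density_growth_factor(susceptible_means, THIRDS)
        assert lam == pytest.approx(51.9923448, abs=1e-6)

    def test_total_kill_leaves_dormant_survival_only(self, susceptible_means):
        acts = YearActions(("early", "early", "early"), None)
        p = dataclasses.replace(susceptible_means, rc_post_early=1.0)
        lam = low_density_growth_factor(p, THIRDS, acts)
        assert lam == pytest.approx(0.1377, abs=1e-9)

    def test_subcritical_growth_implies_zero_equilibrium(self, susceptible_means, strategies):
        lam = cycle_growth_factor(susceptible_means, THIRDS, strategies["M3"])
        assert lam < 1.0
        assert deterministic_equilibrium(susceptible_means, THIRDS, strategies["M3"]) == 0.0


class TestDeterministicEquilibrium:
    def test_single_cohort_near_closed_form_limit(self, susceptible_means):
        # saturation limit f(1-lp)(1-l)/b / (1-(1-e)(1-sm)) = 13460 seeds/m2
        eq = deterministic_equilibrium(susceptible_means, (0.0, 1.0, 0.0))
        assert eq == pytest.approx(13460.3, rel=0.05)

    def test_forward_iteration_reaches_the_fixed_point(self, susceptible_means):
        eq = deterministic_equilibrium(susceptible_means, THIRDS)
        sb = 2000.0
        for _ in range(200):
            sb = annual_sb_map(sb, THIRDS, susceptible_means, NO_ACTION)
        assert sb == pytest.approx(eq, rel=1e-6)

    def test_fixed_point_is_invariant_under_the_map(self, resistant_means):
        eq = deterministic_equilibrium(resistant_means, THIRDS)
        assert annual_sb_map(eq, THIRDS, resistant_means, NO_ACTION) == pytest.approx(
            eq, rel=1e-7
        )

    def test_initial_condition_independence(self, susceptible, strategies):
        finals = []
        for sb0 in (200.0, 2000.0, 20000.0):
            sim = config(susceptible, strategies["M1"], years=200, replicates=1,
                         deterministic=True, fixed_fractions=THIRDS,
                         initial_seed_bank=sb0)
            finals.append(run_replicate(sim, 0).final_seed_bank)
        assert max(finals) / min(finals) - 1 < 0.01


class TestRunReplicate:
    def test_deterministic_trajectory_matches_forward_map(self, susceptible, strategies,
                                                          susceptible_means):
        sim = config(susceptible, strategies["M1"], years=10, replicates=1,
                     deterministic=True, fixed_fractions=THIRDS)
        traj = run_replicate(sim, 0)
        sb = 2000.0
        for state in traj.states:
            assert state.sb == pytest.approx(sb, rel=1e-12)
            sb = annual_sb_map(sb, THIRDS, susceptible_means, NO_ACTION)
        assert traj.final_seed_bank == pytest.approx(sb, rel=1e-12)

    def test_replicate_is_reproducible(self, resistant, strategies):
        sim = config(resistant, strategies["M9"], years=5, master_seed=123)
        a = run_replicate(sim, 4)
        b = run_replicate(sim, 4)
        assert a == b

    def test_replicates_differ_stochastically(self, susceptible, strategies):
        sim = config(susceptible, strategies["M1"], years=5, master_seed=123)
        assert run_replicate(sim, 0).final_seed_bank != run_replicate(sim, 1).final_seed_bank

    def test_empty_seed_bank_is_absorbing(self, susceptible, strategies):
        sim = config(susceptible, strategies["M1"], years=5, replicates=1,
                     initial_seed_bank=0.0, master_seed=9)
        traj = run_replicate(sim, 0)
        assert all(s.sb == 0.0 and s.sb_next == 0.0 for s in traj.states)


class TestRunSimulation:
    def test_deterministic_summary_has_zero_spread(self, susceptible, strategies):
        sim = config(susceptible, strategies["M1"], years=5, replicates=10,
                     deterministic=True)
        summary = run_simulation(sim)
        assert summary.sd_final_sb == 0.0

    def test_summary_mean_is_mean_of_replicate_finals(self, susceptible, strategies):
        sim = config(susceptible, strategies["M5"], years=5, replicates=20, master_seed=2)
        summary = run_simulation(sim)
        finals = [run_replicate(sim, r).final_seed_bank for r in range(20)]
        assert summary.mean_final_sb == pytest.approx(np.mean(finals))
        assert summary.sd_final_sb == pytest.approx(np.std(finals, ddof=1))

    def test_adding_replicates_does_not_perturb_earlier_ones(self, susceptible, strategies):
        small = config(susceptible, strategies["M1"], years=5, replicates=5, master_seed=3)
        large = dataclasses.replace(small, replicates=10)
        for r in range(5):
            assert run_replicate(small, r) == run_replicate(large, r)


class TestPercentReduction:
    def test_reported_style_example(self):
        assert percent_reduction(1009.0, 19121.0) == pytest.approx(94.7, abs=0.05)

    def test_identity_and_total_control(self):
        assert percent_reduction(5.0, 5.0) == 0.0
        assert percent_reduction(0.0, 123.0) == 100.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(1.0, 0.0)


class TestClimateDrivenFractions:
    def test_scenario_offset_advances_emergence(self, susceptible, strategies):
        base = config(susceptible, strategies["M1"], deterministic=True)
        warm = dataclasses.replace(base, scenario=ScenarioConfig("s2", 2.5))
        f1 = deterministic_fractions(base)
        f2 = deterministic_fractions(warm)
        assert f2[0] > f1[0]
        assert f2[2] < f1[2]

    def test_observed_series_matches_equivalent_synthetic(self, susceptible, strategies):
        from loliumsim.climate import generate_synthetic_series

        clim = ClimatologyConfig(13.5, 5.5, daily_noise_sd=0.0)
        series = generate_synthetic_series(clim, "2001-01-01", "2001-12-31")
        synthetic = config(susceptible, strategies["M1"], years=1, replicates=1,
                           deterministic=True, climatology=clim)
        observed = dataclasses.replace(synthetic, temperature_series=series)
        assert run_replicate(observed, 0) == run_replicate(synthetic, 0)

    def test_observed_series_must_cover_the_season(self, susceptible, strategies):
        from loliumsim.climate import generate_synthetic_series

        series = generate_synthetic_series(
            ClimatologyConfig(daily_noise_sd=0.0), "2001-03-01", "2001-05-31"
        )
        sim = config(susceptible, strategies["M1"], years=1, replicates=1,
                     deterministic=True, temperature_series=series)
        with pytest.raises(ValueError, match="emergence season"):
            run_replicate(sim, 0)
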