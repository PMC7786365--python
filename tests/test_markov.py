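import numpy as np
import pytest

from npc_cea.markov import (
    CohortTrace,
    ModelConfig,
    TransitionSchedule,
    UtilitySet,
    build_transition_schedule,
    discounted_accrual,
    life_years,
    qalys,
    run_cohort,
)
from npc_cea.survival import ParametricSurvival

GP_DFS = ParametricSurvival("weibull", 0.00059, 1.48831, "cycles")
GP_OS = ParametricSurvival("exponential", 0.00085, 1.0, "cycles")


def constant_schedule(p_die: float, K: int) -> TransitionSchedule:
    """Toy schedule: no progression, constant death probability."""
    mats = np.zeros((K, 3, 3))
    mats[:, 0, 0] = 1.0 - p_die
    mats[:, 0, 2] = p_die
    mats[:, 1, 1] = 1.0 - p_die
    mats[:, 1, 2] = p_die
    mats[:, 2, 2] = 1.0
    return TransitionSchedule(mats)


class TestModelConfig:
    def test_default_cycle_count(self):
        assert ModelConfig().n_cycles == 173  # floor(10 * 365.25 / 21)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(cycle_length_days=0.0)
        with pytest.raises(ValueError):
            ModelConfig(annual_discount=1.0)
        with pytest.raises(ValueError):
            ModelConfig(horizon_years=0.01)

    def test_cycle_discount_factor(self):
        config = ModelConfig()
        assert config.cycle_discount == pytest.approx(1.03 ** (-21 / 365.25), rel=1e-15)


class TestBuildSchedule:
    @pytest.mark.parametrize("decomposition", ["independent", "partition"])
    def test_rows_stochastic(self, decomposition):
        config = ModelConfig()
        sched = build_transition_schedule(GP_DFS, GP_OS, config, decomposition)
        m = sched.matrices
        assert np.max(np.abs(m.sum(axis=2) - 1.0)) <= 1e-12
        assert np.all((m >= 0) & (m <= 1))
        # death row is exactly absorbing
        assert np.all(m[:, 2] == np.array([0.0, 0.0, 1.0]))

    def test_cohort_deaths_track_overall_survival(self):
        # calibration identity: dead fraction at cycle K equals 1 - S_os(K*u)
        config = ModelConfig()
        sched = build_transition_schedule(GP_DFS, GP_OS, config)
        trace = run_cohort(sched, config)
        u = config.cycle_length_days / GP_OS.unit_days
        expected_dead = 1.0 - GP_OS.survival(np.arange(config.n_cycles + 1) * u)
        assert np.max(np.abs(trace.occupancy[:, 2] - expected_dead)) < 1e-6

    def test_partition_calibration_tracks_os_when_feasible(self):
        # TPF curves: the DFS hazard exceeds the OS hazard from cycle 1,
        # so the PD->Death calibration is feasible throughout
        dfs = ParametricSurvival("weibull", 0.00256, 1.14471, "cycles")
        os_m = ParametricSurvival("weibull", 0.00097, 1.15449, "cycles")
        config = ModelConfig()
        sched = build_transition_schedule(dfs, os_m, config, "partition")
        trace = run_cohort(sched, config)
        u = config.cycle_length_days / os_m.unit_days
        expected_dead = 1.0 - os_m.survival(np.arange(config.n_cycles + 1) * u)
        assert np.max(np.abs(trace.occupancy[:, 2] - expected_dead)) < 1e-6

    def test_partition_infeasible_cycles_warn_and_self_correct(self):
        # GP curves: early DFS hazard is below the OS hazard while PD is
        # still empty, so the death target cannot be met at first; the
        # cumulative calibration recovers once PD is populated
        config = ModelConfig()
        with pytest.warns(RuntimeWarning, match="clamped"):
            sched = build_transition_schedule(GP_DFS, GP_OS, config, "partition")
        trace = run_cohort(sched, config)
        u = config.cycle_length_days / GP_OS.unit_days
        expected_dead = 1.0 - GP_OS.survival(np.arange(config.n_cycles + 1) * u)
        assert abs(trace.occupancy[-1, 2] - expected_dead[-1]) < 1e-6

    def test_independent_occupancy_closed_form(self):
        # DFS occupancy is S_dfs * S_os; alive occupancy is S_os
        config = ModelConfig()
        sched = build_transition_schedule(GP_DFS, GP_OS, config)
        trace = run_cohort(sched, config)
        k = np.arange(config.n_cycles + 1, dtype=float)
        s_dfs = GP_DFS.survival(k)
        s_os = GP_OS.survival(k)
        assert np.max(np.abs(trace.occupancy[:, 0] - s_dfs * s_os)) < 1e-10
        assert np.max(np.abs(1.0 - trace.occupancy[:, 2] - s_os)) < 1e-10

    def test_partition_identical_curves_means_no_progression(self):
        # when the DFS curve is the OS curve every exit is a death
        config = ModelConfig(horizon_years=3.0)
        sched = build_transition_schedule(GP_OS, GP_OS, config, "partition")
        assert np.all(sched.matrices[:, 0, 1] == 0.0)

    def test_negligible_death_hazard(self):
        config = ModelConfig(horizon_years=3.0)
        os_flat = ParametricSurvival("exponential", 1e-15, 1.0, "cycles")
        sched = build_transition_schedule(GP_DFS, os_flat, config)
        trace = run_cohort(sched, config)
        assert np.all(sched.matrices[:, 0, 2] < 1e-12)
        assert np.all(trace.occupancy[:, 2] < 1e-10)


class TestRunCohort:
    def test_identity_schedule_keeps_start(self):
        config = ModelConfig(horizon_years=1.0)
        K = config.n_cycles
        sched = TransitionSchedule(np.tile(np.eye(3), (K, 1, 1)))
        start = np.array([0.5, 0.3, 0.2])
        trace = run_cohort(sched, config, start)
        assert np.all(trace.occupancy == start)

    def test_death_is_absorbing(self):
        config = ModelConfig(horizon_years=1.0)
        sched = build_transition_schedule(GP_DFS, GP_OS, config)
        trace = run_cohort(sched, config, np.array([0.0, 0.0, 1.0]))
        assert np.all(trace.occupancy[:, 2] == 1.0)

    def test_geometric_closed_form(self):
        config = ModelConfig(horizon_years=2.0)
        K = config.n_cycles
        p = 0.03
        trace = run_cohort(constant_schedule(p, K), config)
        expected = (1.0 - p) ** np.arange(K + 1)
        assert np.max(np.abs(trace.occupancy[:, 0] - expected)) < 1e-12

    def test_conservation_and_monotone_death_on_fixture(self):
        config = ModelConfig()
        trace = run_cohort(build_transition_schedule(GP_DFS, GP_OS, config), config)
        assert np.max(np.abs(trace.occupancy.sum(axis=1) - 1.0)) <= 1e-12
        assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-15)

    def test_short_schedule_rejected(self):
        config = ModelConfig()
        sched = TransitionSchedule(np.tile(np.eye(3), (10, 1, 1)))
        with pytest.raises(ValueError, match="schedule"):
            run_cohort(sched, config)

    def test_bad_start_rejected(self):
        config = ModelConfig(horizon_years=1.0)
        sched = TransitionSchedule(np.tile(np.eye(3), (config.n_cycles, 1, 1)))
        with pytest.raises(ValueError):
            run_cohort(sched, config, np.array([0.5, 0.5, 0.5]))


class TestAccrual:
    def test_everyone_alive_no_discount_gives_horizon(self):
        config = ModelConfig(horizon_years=1.0, annual_discount=0.0)
        K = config.n_cycles
        sched = TransitionSchedule(np.tile(np.eye(3), (K, 1, 1)))
        trace = run_cohort(sched, config)
        total, _ = life_years(trace, config)
        assert total == pytest.approx(K * config.cycle_years, rel=1e-12)

    def test_matches_geometric_series_closed_form(self):
        # all-exponential toy: sum_k (v*(1-p))^k * cycle_years
        config = ModelConfig(horizon_years=2.0)
        K = config.n_cycles
        p = 0.02
        v = config.cycle_discount
        trace = run_cohort(constant_schedule(p, K), config)
        total, _ = life_years(trace, config)
        q = v * (1.0 - p)
        expected = config.cycle_years * (1.0 - q**K) / (1.0 - q)
        assert total == pytest.approx(expected, abs=1e-10)

    def test_qaly_definition_on_toy_trace(self):
        config = ModelConfig(horizon_years=1.0)
        K = config.n_cycles
        occ = np.tile(np.array([0.6, 0.3, 0.1]), (K + 1, 1))
        trace = CohortTrace(occ)
        utilities = UtilitySet(0.76, 0.57)
        total, by_state = qalys(trace, utilities, config)
        disc = config.discount_factors()
        u_yr = config.cycle_years
        expected_dfs = 0.76 * (disc * 0.6).sum() * u_yr
        expected_pd = 0.57 * (disc * 0.3).sum() * u_yr
        assert by_state[0] == pytest.approx(expected_dfs, rel=1e-12)
        assert by_state[1] == pytest.approx(expected_pd, rel=1e-12)
        assert total == pytest.approx(expected_dfs + expected_pd, rel=1e-12)

    def test_totals_decrease_with_discount_rate(self):
        totals = []
        for rate in (0.0, 0.03, 0.08):
            config = ModelConfig(annual_discount=rate)
            sched = build_transition_schedule(GP_DFS, GP_OS, config)
            trace = run_cohort(sched, config)
            totals.append(life_years(trace, config)[0])
        assert totals[0] > totals[1] > totals[2]

    def test_qaly_never_exceeds_life_years(self):
        config = ModelConfig()
        trace = run_cohort(build_transition_schedule(GP_DFS, GP_OS, config), config)
        ly, _ = life_years(trace, config)
        q, _ = qalys(trace, UtilitySet(0.76, 0.57), config)
        assert q <= ly

    def test_half_cycle_correction_averages_neighbours(self):
        config = ModelConfig(horizon_years=1.0, half_cycle_correction=True)
        K = config.n_cycles
        trace = run_cohort(constant_schedule(0.05, K), config)
        total_hc, _ = life_years(trace, config)
        plain_config = ModelConfig(horizon_years=1.0)
        total, _ = life_years(trace, plain_config)
        assert total_hc < total  # start-of-cycle occupancy overstates survival

    def test_mismatched_rewards_rejected(self):
        config = ModelConfig(horizon_years=1.0)
        trace = run_cohort(constant_schedule(0.05, config.n_cycles), config)
        with pytest.raises(ValueError):
            discounted_accrual(trace, np.zeros((3, 3)), config)


class TestUtilitySet:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            UtilitySet(0.5, 0.6)
        with pytest.raises(ValueError):
            UtilitySet(0.76, 0.57, u_dead=0.1)

    def test_trace_csv_round_trip(self, tmp_path):
        config = ModelConfig(horizon_years=1.0)
        trace = run_cohort(constant_schedule(0.05, config.n_cycles), config)
        path = tmp_path / "trace.csv"
        trace.to_csv(path, config)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["cycle", "dfs", "pd", "dead", "discount_factor"]
        assert len(df) == config.n_cycles + 1
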