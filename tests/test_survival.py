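import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter, WeibullFitter

from npc_cea.survival import (
    DigitizedCurve,
    FittingError,
    ParametricSurvival,
    PseudoIPD,
    ReconstructionError,
    anchor_table,
    cycle_transition_prob,
    fit_digitized_ls,
    fit_parametric,
    km_estimate,
    reconstruct_pseudo_ipd,
    survival_at,
)
from npc_cea.synthetic import SimSpec, simulate_ipd

WEIBULL_GP_DFS = ParametricSurvival("weibull", 0.00059, 1.48831, "cycles")
EXP_GP_OS = ParametricSurvival("exponential", 0.00085, 1.0, "cycles")


class TestSurvivalAt:
    @pytest.mark.parametrize("model", [WEIBULL_GP_DFS, EXP_GP_OS])
    def test_starts_at_one(self, model):
        assert survival_at(model, 0.0) == 1.0

    def test_weibull_closed_form(self):
        # direct evaluation of exp(-0.00059 * 36**1.48831)
        expected = math.exp(-0.00059 * 36**1.48831)
        assert survival_at(WEIBULL_GP_DFS, 36.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.885, abs=5e-4)

    def test_exponential_closed_form(self):
        assert survival_at(EXP_GP_OS, 12.0) == pytest.approx(math.exp(-0.0102), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(WEIBULL_GP_DFS, -1.0)

    @pytest.mark.parametrize("model", [WEIBULL_GP_DFS, EXP_GP_OS])
    def test_positive_and_non_increasing_on_grid(self, model):
        s = model.survival(np.linspace(0.0, 400.0, 1000))
        assert np.all(s > 0)
        assert np.all(np.diff(s) <= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParametricSurvival("weibull", -0.1, 1.0)
        with pytest.raises(ValueError):
            ParametricSurvival("exponential", 0.001, 2.0)
        with pytest.raises(ValueError):
            ParametricSurvival("gompertz", 0.001, 1.0)


class TestCycleTransitionProb:
    def test_exponential_constant_hazard_identity(self):
        model = ParametricSurvival("exponential", 0.00085, 1.0, "months")
        expected = 1.0 - math.exp(-0.00085 * 0.690)
        tps = [cycle_transition_prob(model, k, 0.690) for k in (1, 2, 50, 173)]
        assert tps[0] == pytest.approx(expected, rel=1e-12)
        # exact invariance to cycle index
        assert all(tp == tps[0] for tp in tps)

    def test_first_cycle_equals_one_minus_survival(self):
        u = 1.0
        tp1 = cycle_transition_prob(WEIBULL_GP_DFS, 1, u)
        assert tp1 == pytest.approx(1.0 - float(WEIBULL_GP_DFS.survival(u)), rel=1e-12)

    def test_increasing_hazard_for_shape_above_one(self):
        tps = [cycle_transition_prob(WEIBULL_GP_DFS, k, 1.0) for k in range(1, 174)]
        assert np.all(np.diff(tps) >= 0)

    @pytest.mark.parametrize("model", [WEIBULL_GP_DFS, EXP_GP_OS])
    def test_product_identity(self, model):
        # prod_k (1 - tp(k)) telescopes to S(K*u)/S(0)
        u, K = 1.0, 173
        prod = np.prod([1.0 - cycle_transition_prob(model, k, u) for k in range(1, K + 1)])
        assert prod == pytest.approx(float(model.survival(K * u)), abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cycle_transition_prob(WEIBULL_GP_DFS, 0, 1.0)
        with pytest.raises(ValueError):
            cycle_transition_prob(WEIBULL_GP_DFS, 1, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(1e-5, 0.1),
        shape=st.floats(0.3, 3.0),
        k=st.integers(1, 200),
    )
    def test_probability_bounds(self, scale, shape, k):
        model = ParametricSurvival("weibull", scale, shape)
        tp = cycle_transition_prob(model, k, 1.0)
        assert 0.0 <= tp < 1.0


class TestReconstruction:
    def test_pure_event_interval_is_exact(self):
        curve = DigitizedCurve(
            "toy",
            points=[(1.0, 0.9)],
            at_risk=[(0.0, 100), (2.0, 90)],
        )
        ipd = reconstruct_pseudo_ipd(curve, [0.0, 2.0])
        assert ipd.n_events == 10
        # everyone else administratively censored at the last boundary
        assert len(ipd) == 100

    def test_empty_interval_yields_nothing(self):
        curve = DigitizedCurve(
            "flat", points=[(1.0, 1.0)], at_risk=[(0.0, 50), (2.0, 50)]
        )
        ipd = reconstruct_pseudo_ipd(curve, [0.0, 2.0])
        assert ipd.n_events == 0
        assert np.all(ipd.times == 2.0)

    def test_inconsistent_inputs_identify_interval(self):
        # survival says 10 events but the risk set only lost 5 -> negative censorings
        curve = DigitizedCurve(
            "bad", points=[(1.0, 0.9)], at_risk=[(0.0, 100), (2.0, 96)]
        )
        with pytest.raises(ReconstructionError, match=r"\[0.0, 2.0\)"):
            reconstruct_pseudo_ipd(curve, [0.0, 2.0])

    def test_km_boundary_round_trip(self):
        # KM recomputed from the reconstruction matches the digitized values
        model = ParametricSurvival("weibull", 0.005, 1.3)
        ipd = simulate_ipd(SimSpec(model, 200, ("uniform", 120.0), seed=7))
        bounds = [0.0, 20.0, 40.0, 60.0, 80.0]
        curve = km_estimate(ipd, at_risk_times=bounds)
        rec = reconstruct_pseudo_ipd(curve, bounds)
        kmf = KaplanMeierFitter().fit(rec.times, rec.events)
        for b in bounds[1:]:
            n_at_b = curve.n_at_risk(bounds[0])
            km_val = float(kmf.survival_function_at_times(b).iloc[0])
            assert km_val == pytest.approx(curve.survival_at(b), abs=1.5 / n_at_b)

    def test_parameter_recovery_through_reconstruction(self):
        model = ParametricSurvival("weibull", 0.002, 1.4)
        ipd = simulate_ipd(SimSpec(model, 150, ("uniform", 150.0), seed=11))
        bounds = list(np.linspace(0.0, 90.0, 10))
        curve = km_estimate(ipd, at_risk_times=bounds)
        rec = reconstruct_pseudo_ipd(curve, bounds)
        fit = fit_parametric(rec, "weibull")
        assert abs(fit.model.scale - model.scale) < 2 * fit.scale_se
        assert abs(fit.model.shape - model.shape) < 2 * fit.shape_se


class TestFitParametric:
    def test_exponential_consistency_large_n(self):
        ipd = simulate_ipd(
            SimSpec(ParametricSurvival("exponential", 0.00085), 10_000, ("none",), seed=3)
        )
        fit = fit_parametric(ipd, "exponential")
        assert fit.model.scale == pytest.approx(0.00085, rel=0.03)
        assert fit.shape_se is None

    def test_weibull_recovery_with_censoring(self):
        model = ParametricSurvival("weibull", 0.00256, 1.14471)
        # uniform censoring tuned to roughly 30% censored records
        ipd = simulate_ipd(SimSpec(model, 150, ("uniform", 600.0), seed=5))
        censored_frac = 1.0 - ipd.n_events / len(ipd)
        assert 0.15 < censored_frac < 0.45
        fit = fit_parametric(ipd, "weibull")
        assert abs(fit.model.scale - model.scale) < 2 * fit.scale_se
        assert abs(fit.model.shape - model.shape) < 2 * fit.shape_se
        # estimate correlation is strongly negative, as for any such fit
        assert fit.param_correlation < -0.8

    def test_exponential_mean_absolute_relative_error(self):
        # 20 seeded replicates at n=500: MARE of the scale estimate < 10%
        errs = []
        for seed in range(20):
            ipd = simulate_ipd(
                SimSpec(ParametricSurvival("exponential", 0.00085), 500, ("none",), seed)
            )
            fit = fit_parametric(ipd, "exponential")
            errs.append(abs(fit.model.scale - 0.00085) / 0.00085)
        assert np.mean(errs) < 0.10

    def test_matches_lifelines_weibull(self):
        # independent route: lifelines parameterizes S(t) = exp(-(t/lambda)^rho)
        model = ParametricSurvival("weibull", 0.003, 1.3)
        ipd = simulate_ipd(SimSpec(model, 400, ("uniform", 200.0), seed=9))
        ours = fit_parametric(ipd, "weibull")
        wf = WeibullFitter().fit(ipd.times, ipd.events)
        theirs_scale = wf.lambda_ ** (-wf.rho_)
        assert ours.model.shape == pytest.approx(wf.rho_, rel=1e-4)
        assert ours.model.scale == pytest.approx(theirs_scale, rel=1e-3)

    def test_all_censored_rejected(self):
        ipd = PseudoIPD(np.linspace(1, 10, 10), np.zeros(10, dtype=int))
        with pytest.raises(FittingError):
            fit_parametric(ipd, "exponential")

    def test_single_event_time_unidentifiable(self):
        ipd = PseudoIPD(np.array([5.0, 5.0, 5.0, 7.0]), np.array([1, 1, 1, 0]))
        with pytest.raises(FittingError):
            fit_parametric(ipd, "weibull")

    def test_least_squares_path_on_clean_curve(self):
        model = ParametricSurvival("weibull", 0.002, 1.4)
        t = np.linspace(5.0, 120.0, 20)
        curve = DigitizedCurve("exact", points=list(zip(t, model.survival(t))))
        fitted = fit_digitized_ls(curve, "weibull")
        assert fitted.scale == pytest.approx(model.scale, rel=1e-6)
        assert fitted.shape == pytest.approx(model.shape, rel=1e-6)


class TestAnchorTable:
    def test_three_year_landmarks(self):
        # the time-unit convention is auditable against observed 3-year KM values
        table = anchor_table(
            {"gp_dfs": WEIBULL_GP_DFS, "gp_os": EXP_GP_OS},
            {"gp_dfs": (3.0, 0.831), "gp_os": (3.0, 0.944)},
        )
        gp_dfs = table.set_index("curve").loc["gp_dfs"]
        assert gp_dfs["model_survival"] == pytest.approx(0.809, abs=2e-3)
        assert abs(gp_dfs["model_survival"] - gp_dfs["reference_survival"]) < 0.03


class TestCurveContainers:
    def test_digitized_curve_validation(self):
        with pytest.raises(ValueError):
            DigitizedCurve("bad", points=[(1.0, 0.5), (2.0, 0.6)])
        with pytest.raises(ValueError):
            DigitizedCurve("bad", points=[(2.0, 0.9), (1.0, 0.8)])

    def test_csv_round_trips(self, tmp_path):
        curve = DigitizedCurve(
            "c", points=[(1.0, 0.9), (2.0, 0.8)], at_risk=[(0.0, 100), (2.0, 70)]
        )
        curve.to_csv(tmp_path / "c.csv", tmp_path / "c_ar.csv")
        back = DigitizedCurve.from_csv(tmp_path / "c.csv", tmp_path / "c_ar.csv")
        assert back.points == curve.points
        assert back.at_risk == curve.at_risk

        ipd = PseudoIPD(np.array([1.0, 2.0]), np.array([1, 0]))
        ipd.to_csv(tmp_path / "ipd.csv")
        back_ipd = PseudoIPD.from_csv(tmp_path / "ipd.csv")
        assert np.array_equal(back_ipd.times, ipd.times)
        assert np.array_equal(back_ipd.events, ipd.events)
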