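"""Growth-curve engine: linearization, fitting, ranking, parameters."""

import numpy as np
import pytest

from phenomod.exceptions import DegenerateFitError, StressFitError, ValidationError
from phenomod.growth import (
    CONTROL_MODELS,
    GrowthCurveModel,
    GrowthTrajectory,
    derive_growth_parameters,
    fit_all_control_models,
    fit_growth_model,
    fit_recovery_phase,
    fit_stress_phase,
    linearize_trajectory,
    predict_trajectory,
)

from conftest import CONTROL_CURVES, logistic_curve

ASYMPTOTE_MODELS = {"monomolecular", "logistic", "gompertz", "weibull"}


class TestTrajectoryValidation:
    def test_requires_four_points(self):
        with pytest.raises(ValidationError):
            GrowthTrajectory("p", [1, 2, 3], [1, 2, 3])

    def test_times_strictly_increasing(self):
        with pytest.raises(ValidationError):
            GrowthTrajectory("p", [1, 2, 2, 3], [1, 2, 3, 4])

    def test_finite_values(self):
        with pytest.raises(ValidationError):
            GrowthTrajectory("p", [1, 2, 3, 4], [1, 2, np.nan, 4])


class TestLinearization:
    def test_logistic_midpoint_maps_to_zero(self, logistic_trajectory):
        # y = K/2 gives ln(K/y - 1) = ln 1 = 0
        x, ystar, mask = linearize_trajectory(logistic_trajectory, "logistic", K=100.0)
        at_t0 = np.isclose(x, 25.0)
        assert np.allclose(ystar[at_t0], 0.0, atol=1e-12)

    def test_exponential_exactly_linear(self):
        t = np.arange(0.0, 11.0)
        traj = GrowthTrajectory("p", t, 2.0 * np.exp(0.1 * t))
        x, ystar, mask = linearize_trajectory(traj, "exponential")
        assert mask.all()
        assert np.allclose(ystar, np.log(2.0) + 0.1 * t, atol=1e-12)

    def test_monomolecular_masks_values_above_K(self):
        traj = GrowthTrajectory("p", [1, 2, 3, 4, 5], [2, 5, 8, 12, 9])
        x, ystar, mask = linearize_trajectory(traj, "monomolecular", K=10.0)
        assert mask.tolist() == [True, True, True, False, True]

    def test_too_few_valid_points_is_degenerate(self):
        traj = GrowthTrajectory("p", [1, 2, 3, 4], [-1, -2, 5, 6])
        with pytest.raises(DegenerateFitError, match="exponential"):
            linearize_trajectory(traj, "exponential")

    def test_masking_conserves_counts(self, days):
        vals = logistic_curve(days).copy()
        vals[:3] = -1.0  # imaging zeros/negatives at early time points
        traj = GrowthTrajectory("p", days, vals)
        fit = fit_growth_model(traj, "exponential")
        assert fit.n_used + fit.n_masked == len(traj)
        assert fit.n_masked == 3


class TestFitting:
    @pytest.mark.parametrize("model_id", CONTROL_MODELS)
    def test_noise_free_round_trip(self, model_id, days):
        true_params, curve = CONTROL_CURVES[model_id]
        fit = fit_growth_model(GrowthTrajectory("p", days, curve(days)), model_id)
        assert fit.rsquared_linearized == pytest.approx(1.0, abs=1e-9)
        tol = 1e-4 if model_id in ASYMPTOTE_MODELS else 1e-9
        for name, truth in true_params.items():
            assert fit.params[name] == pytest.approx(truth, rel=tol), name

    def test_exponential_coefficients_machine_precision(self, days):
        traj = GrowthTrajectory("p", days, 2.0 * np.exp(0.1 * days))
        fit = fit_growth_model(traj, "exponential")
        assert fit.params["a"] == pytest.approx(2.0, rel=1e-12)
        assert fit.params["b"] == pytest.approx(0.1, rel=1e-12)

    def test_linear_identity_case(self):
        t = np.arange(0.0, 11.0)
        traj = GrowthTrajectory("p", t, 3.0 + 2.0 * t)
        fit = fit_growth_model(traj, "linear")
        assert fit.params == pytest.approx({"a": 3.0, "b": 2.0})
        assert fit.rsquared_original == pytest.approx(1.0)
        assert np.allclose(fit.fitted, traj.values)

    def test_constant_response_errors(self):
        traj = GrowthTrajectory("p", [1, 2, 3, 4], [5, 5, 5, 5])
        with pytest.raises(DegenerateFitError):
            fit_growth_model(traj, "linear")

    def test_pvalue_in_unit_interval(self, days):
        rng = np.random.default_rng(0)
        traj = GrowthTrajectory("p", days, logistic_curve(days) + rng.normal(0, 2, days.size))
        for mid in CONTROL_MODELS:
            fit = fit_growth_model(traj, mid)
            assert 0 < fit.pvalue <= 1
            assert fit.rsquared_linearized <= 1


class TestRanking:
    @pytest.mark.parametrize("model_id", CONTROL_MODELS)
    def test_generative_model_ranks_first(self, model_id, days):
        _, curve = CONTROL_CURVES[model_id]
        fits, failures = fit_all_control_models(GrowthTrajectory("p", days, curve(days)))
        best_r2 = fits[0].rsquared_original
        own = next(f for f in fits if f.model_id == model_id)
        # ties only with models that nest the generative curve
        assert own.rsquared_original == pytest.approx(best_r2, abs=1e-9)

    def test_failures_reported_not_dropped(self, days):
        vals = logistic_curve(days).copy()
        vals[0] = -5.0
        fits, failures = fit_all_control_models(GrowthTrajectory("p", days, vals))
        assert len(fits) + len(failures) == len(CONTROL_MODELS)

    def test_four_point_masking_count(self):
        traj = GrowthTrajectory("p", [1, 2, 3, 4], [-1.0, 10.0, 20.0, 35.0])
        fit = fit_growth_model(traj, "exponential")
        assert fit.n_used == 3


class TestGrowthParameters:
    def test_logistic_direct_mapping(self, logistic_trajectory):
        gp = derive_growth_parameters(fit_growth_model(logistic_trajectory, "logistic"))
        assert gp.R == pytest.approx(0.2, rel=1e-6)
        assert gp.IP == pytest.approx(25.0, rel=1e-6)
        assert gp.K_max == pytest.approx(100.0, rel=1e-6)

    def test_gompertz_inflection_closed_form(self, days):
        # d2y/dt2 = 0 at t = ln(a)/r for y = K exp(-a e^{-rt})
        curve = 100.0 * np.exp(-5.0 * np.exp(-0.3 * days))
        gp = derive_growth_parameters(
            fit_growth_model(GrowthTrajectory("p", days, curve), "gompertz"))
        assert gp.IP == pytest.approx(np.log(5.0) / 0.3, rel=1e-2)

    def test_linear_has_no_inflection(self, days):
        traj = GrowthTrajectory("p", days, 3.0 + 2.0 * days)
        gp = derive_growth_parameters(fit_growth_model(traj, "linear"))
        assert gp.IP is None
        assert gp.notes  # explanatory note, not an exception
        assert gp.R == pytest.approx(2.0)
        assert gp.K_max == pytest.approx(3.0 + 2.0 * days[-1])


class TestPredict:
    def test_logistic_inflection_value_is_half_K(self, logistic_trajectory):
        fit = fit_growth_model(logistic_trajectory, "logistic")
        assert predict_trajectory(fit, [25.0])[0] == pytest.approx(50.0, rel=1e-6)

    @pytest.mark.parametrize("model_id", CONTROL_MODELS)
    def test_predict_at_input_times_equals_fitted(self, model_id, days):
        _, curve = CONTROL_CURVES[model_id]
        fit = fit_growth_model(GrowthTrajectory("p", days, curve(days)), model_id)
        assert np.array_equal(predict_trajectory(fit, days), fit.fitted)

    def test_logistic_asymptote(self, logistic_trajectory):
        fit = fit_growth_model(logistic_trajectory, "logistic")
        assert predict_trajectory(fit, [1000.0])[0] == pytest.approx(fit.params["K"], abs=1e-6)

    def test_nonfinite_times_rejected(self, logistic_trajectory):
        fit = fit_growth_model(logistic_trajectory, "logistic")
        with pytest.raises(ValidationError):
            predict_trajectory(fit, [1.0, np.inf])


class TestStressPhase:
    def test_noise_free_gaussian_bell_exact(self):
        t = np.arange(5.0, 36.0)
        y = 50.0 * np.exp(-((t - 20.0) ** 2) / 50.0)
        sf = fit_stress_phase(GrowthTrajectory("p", t, y, condition="stress"), (5.0, 35.0))
        assert sf.best_phase1 == "bell_gauss"
        assert sf.phase1_fits["bell_gauss"].rsquared_original == pytest.approx(1.0, abs=1e-9)
        assert sf.peak_time == pytest.approx(20.0, abs=1e-9)
        assert sf.peak_value == pytest.approx(50.0, abs=1e-9)

    def test_noise_free_quadratic_vertex(self):
        t = np.arange(1.0, 40.0)
        y = 1.0 + 4.0 * t - 0.1 * t**2
        traj = GrowthTrajectory("p", t[y > 0], y[y > 0], condition="stress")
        sf = fit_stress_phase(traj, (traj.times[0], traj.times[-1]))
        q = sf.phase1_fits["quadratic"]
        assert q.rsquared_original == pytest.approx(1.0, abs=1e-9)
        vertex = -q.params["c1"] / (2 * q.params["c2"])
        assert vertex == pytest.approx(20.0, abs=1e-6)

    def test_upward_opening_data_flags_curvature(self):
        t = np.arange(1.0, 12.0)
        traj = GrowthTrajectory("p", t, t**2, condition="stress")
        sf_or_err = None
        try:
            sf_or_err = fit_stress_phase(traj, (1.0, 11.0))
        except StressFitError:
            return  # every candidate invalid is acceptable
        for mid in ("quadratic", "bell_sqrtgauss", "bell_loggauss"):
            assert mid in sf_or_err.invalid
        # bell_gauss follows the curvature rule: ln(t^2) is concave in t
        c2 = sf_or_err.phase1_fits["bell_gauss"].params["c2"]
        assert ("bell_gauss" in sf_or_err.invalid) == (c2 > -1e-10 * 10)

    def test_window_needs_five_points(self, days):
        traj = GrowthTrajectory("p", days, logistic_curve(days), condition="stress")
        with pytest.raises(ValidationError):
            fit_stress_phase(traj, (1.0, 4.0))


class TestRecoveryPhase:
    def test_exact_line(self):
        t = np.arange(0.0, 21.0)
        traj = GrowthTrajectory("p", t, 10.0 + 3.0 * t)
        fit = fit_recovery_phase(traj, (0.0, 20.0))
        assert fit.params["slope"] == pytest.approx(3.0, abs=1e-12)
        assert fit.rsquared_original == pytest.approx(1.0)

    def test_constant_recovery_slope_zero(self):
        traj = GrowthTrajectory("p", [1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        fit = fit_recovery_phase(traj, (1.0, 5.0))
        assert fit.params["slope"] == 0.0

    def test_noisy_slope_within_sampling_error(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 10, 20)
        traj = GrowthTrajectory("p", t, 10.0 + 3.0 * t + rng.normal(0, 0.1, 20))
        fit = fit_recovery_phase(traj, (0.0, 10.0))
        assert 2.9 < fit.params["slope"] < 3.1

    def test_too_few_points(self):
        traj = GrowthTrajectory("p", [1, 2, 3, 10, 11], [1, 2, 3, 4, 5])
        with pytest.raises(ValidationError):
            fit_recovery_phase(traj, (9.0, 11.0))


def test_noisy_logistic_parameter_recovery():
    """5% multiplicative noise, 30 time points: median relative error < 10%."""
    from phenomod.simulate import simulate_growth_trajectory

    t = np.linspace(1, 50, 30)
    K, r, t0 = 100.0, 0.2, 25.0
    errs = {"K": [], "r": [], "t0": []}
    for seed in range(20):
        traj, _ = simulate_growth_trajectory(
            "logistic", dict(K=K, r=r, t0=t0), t, 0.05, seed, multiplicative=True)
        fit = fit_growth_model(traj, "logistic")
        errs["K"].append(abs(fit.params["K"] - K) / K)
        errs["r"].append(abs(fit.params["r"] - r) / r)
        errs["t0"].append(abs(fit.params["t0"] - t0) / t0)
    for name, e in errs.items():
        assert np.median(e) < 0.10, name
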