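"""Fit costs, estimator limits, lambda sweep and knee selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemovol import (
    IndividualizedModel,
    MeasurementSet,
    ModelParameters,
    NoiseModel,
    ParameterBounds,
    Prior,
    SubjectRecord,
    cost_j1,
    regularizer_j2,
    select_lambda,
    simulate_subject,
)
from hemovol.estimation import FitResult, LambdaSweep
from hemovol.parameters import PARAM_NAMES


def _measurements_from_truth(res, mask, offsets=None):
    """Measurement set equal to the simulated truth plus per-signal offsets."""
    offsets = offsets or {}
    times = {s: res.time.copy() for s in ("bv", "co", "map")}
    values = {s: res.signal(s) + offsets.get(s, 0.0) for s in ("bv", "co", "map")}
    return MeasurementSet(times, values, frozenset(mask))


class TestCostJ1:
    def test_zero_when_model_equals_data(self, mode_params, baseline_context,
                                         hemorrhage_schedule, sampling_grid, noise):
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                               sampling_grid, method="fast", step=0.5)
        ms = _measurements_from_truth(res, {"bv", "co", "map"})
        j1 = cost_j1(mode_params, ms, noise, baseline_context, hemorrhage_schedule,
                     sim_step=0.5)
        assert j1 == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_weighting(self, mode_params, baseline_context,
                                     hemorrhage_schedule, noise):
        # one MAP sample off by 10 mmHg at sigma 5 contributes (10/5)^2 = 4
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                               np.array([0.0]), method="fast", step=0.5)
        ms = MeasurementSet({"map": np.array([0.0])},
                            {"map": res.map + 10.0}, frozenset({"map"}))
        j1 = cost_j1(mode_params, ms, noise, baseline_context, hemorrhage_schedule,
                     sim_step=0.5)
        assert j1 == pytest.approx(4.0, abs=1e-9)

    def test_sum_of_squared_normalized_errors(self, mode_params, baseline_context,
                                              hemorrhage_schedule):
        nm = NoiseModel(sigma_map=1.0)
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                               np.array([0.0, 5.0]), method="fast", step=0.5)
        ms = MeasurementSet({"map": np.array([0.0, 5.0])},
                            {"map": res.map + np.array([3.0, 4.0])}, frozenset({"map"}))
        j1 = cost_j1(mode_params, ms, nm, baseline_context, hemorrhage_schedule,
                     sim_step=0.5)
        assert j1 == pytest.approx(25.0, abs=1e-9)

    def test_masked_signals_do_not_enter(self, mode_params, baseline_context,
                                         hemorrhage_schedule, sampling_grid, noise):
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                               sampling_grid, method="fast", step=0.5)
        # corrupt BV heavily but mask it out: J1 must ignore it
        ms = _measurements_from_truth(res, {"map"}, offsets={"bv": 5.0})
        j1 = cost_j1(mode_params, ms, noise, baseline_context, hemorrhage_schedule,
                     sim_step=0.5)
        assert j1 == pytest.approx(0.0, abs=1e-12)


class TestRegularizerJ2:
    def test_zero_at_mode(self, mode_params, bounds):
        assert regularizer_j2(mode_params, Prior(mode_params, bounds, 2.0)) == 0.0

    def test_full_range_deviation_scales_with_lambda(self, mode_params, bounds):
        theta = mode_params.replace(MAP_target=bounds.upper[-1])
        frac = (bounds.upper[-1] - mode_params.MAP_target) / bounds.ranges[-1]
        j2 = regularizer_j2(theta, Prior(mode_params, bounds, 0.5))
        assert j2 == pytest.approx(0.5 * frac, rel=1e-12)

    def test_sums_normalized_deviations(self, mode_params, bounds):
        theta = mode_params.replace(
            K_p=mode_params.K_p + 0.2 * bounds.ranges[2],
            eta=mode_params.eta + 0.3 * bounds.ranges[7],
        )
        j2 = regularizer_j2(theta, Prior(mode_params, bounds, 1.0))
        assert j2 == pytest.approx(0.5, rel=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_joint_rescaling(self, mode_params, bounds, scale):
        # rescaling one coordinate and its bounds jointly leaves J2 unchanged
        i = PARAM_NAMES.index("A")
        theta = mode_params.replace(A=mode_params.A * 1.2)
        j2 = regularizer_j2(theta, Prior(mode_params, bounds, 1.0))
        lo, hi = bounds.lower.copy(), bounds.upper.copy()
        lo[i] *= scale
        hi[i] *= scale
        scaled_bounds = ParameterBounds(lo, hi)
        theta_s = theta.replace(A=theta.A * scale)
        mode_s = mode_params.replace(A=mode_params.A * scale)
        j2_s = regularizer_j2(theta_s, Prior(mode_s, scaled_bounds, 1.0))
        assert j2_s == pytest.approx(j2, rel=1e-9)


@pytest.fixture()
def case1_subject(small_cohort):
    return small_cohort[0].record.with_case(1)


class TestEstimatorLimits:

    def test_huge_lambda_returns_population_mode(self, case1_subject, mode_params, bounds, noise):
        prior = Prior(mode_params, bounds, 0.0)
        est = IndividualizedModel(prior=prior, lam=1e6, noise=noise, n_starts=1,
                                  maxfev=400).fit(case1_subject)
        assert est.d_ < 1e-3
        np.testing.assert_allclose(est.theta_.to_array(), mode_params.to_array(),
                                   rtol=1e-2, atol=1e-6)

    def test_consistent_optimum_on_noise_free_mode_data(self, mode_params, bounds,
                                                        baseline_context,
                                                        hemorrhage_schedule,
                                                        sampling_grid, noise):
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                               sampling_grid, method="fast", step=0.5)
        ms = _measurements_from_truth(res, {"bv", "co", "map"})
        rec = SubjectRecord(ms, baseline_context, hemorrhage_schedule)
        prior = Prior(mode_params, bounds, 0.0)
        est = IndividualizedModel(prior=prior, lam=0.5, noise=noise, n_starts=1,
                                  maxfev=600).fit(rec)
        assert est.j1_ == pytest.approx(0.0, abs=1e-6)
        assert est.d_ < 1e-4

    def test_lambda_zero_is_pure_likelihood(self, case1_subject, mode_params, bounds, noise):
        prior = Prior(mode_params, bounds, 0.0)
        est = IndividualizedModel(prior=prior, lam=0.0, noise=noise, n_starts=1,
                                  maxfev=300).fit(case1_subject)
        assert est.j2_ == 0.0
        assert est.result_.objective == est.j1_
        # the fitted objective actually is J1 at theta_hat
        j1 = cost_j1(est.theta_, case1_subject.measurements, noise, case1_subject.context,
                     case1_subject.schedule, sim_step=0.5)
        assert j1 == pytest.approx(est.j1_, rel=1e-12)


def _sweep_from_curves(lams, j1s, ds):
    fits = [
        FitResult(theta=None, j1=float(j1), j2=float(lam * d), d=float(d), lam=float(lam))
        for lam, j1, d in zip(lams, j1s, ds)
    ]
    return LambdaSweep(lambdas=np.asarray(lams, dtype=float), fits=fits)


class TestSelectLambda:
    def test_exact_corner_selected(self):
        lams = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        j1 = np.array([0.0, 0.01, 0.02, 0.03, 0.6, 1.0])
        d = np.array([1.0, 0.7, 0.4, 0.1, 0.05, 0.0])
        lam_star, idx, degenerate = select_lambda(_sweep_from_curves(lams, j1, d))
        assert idx == 3 and lam_star == pytest.approx(0.3)
        assert not degenerate

    def test_constant_j1_degenerates_to_smallest_nonzero(self):
        lams = np.array([0.0, 0.1, 0.2, 0.3])
        sweep = _sweep_from_curves(lams, np.ones(4), np.array([1.0, 0.6, 0.3, 0.0]))
        lam_star, idx, degenerate = select_lambda(sweep)
        assert degenerate
        assert lam_star == pytest.approx(0.1) and idx == 1

    def test_smooth_convex_curve_matches_curvature_oracle(self):
        # J1 = lam^2, D = 1/(1+lam): knee via max curvature of the
        # normalized parametric curve, computed independently
        lams = np.geomspace(0.05, 5.0, 40)
        lams = np.concatenate([[0.0], lams])
        j1 = lams**2
        d = 1.0 / (1.0 + lams)
        lam_star, idx, _ = select_lambda(_sweep_from_curves(lams, j1, d))

        x = (j1 - j1.min()) / (j1.max() - j1.min())
        y = (d - d.min()) / (d.max() - d.min())
        dx, dy = np.gradient(x), np.gradient(y)
        ddx, ddy = np.gradient(dx), np.gradient(dy)
        curvature = np.abs(dx * ddy - dy * ddx) / (dx**2 + dy**2) ** 1.5
        curvature[0] = curvature[-1] = 0.0  # endpoint gradients are one-sided
        k_idx = int(np.argmax(curvature))
        assert abs(idx - k_idx) <= 1

    def test_needs_enough_points(self):
        sweep = _sweep_from_curves([0.0, 0.1], [0.0, 1.0], [1.0, 0.0])
        with pytest.raises(ValueError):
            select_lambda(sweep)
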