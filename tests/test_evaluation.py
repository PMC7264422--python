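"""Error metrics e1/e2, deviation distance, signed-rank testing."""

import itertools

import numpy as np
import pytest

from hemovol import (
    MeasurementSet,
    NoiseModel,
    Prior,
    deviation_distance,
    output_error_e1,
    paired_signed_rank_bonferroni,
    state_error_e2,
)
from hemovol.evaluation import normalized_deviations


def _single_signal_set(signal, times, values, mask):
    return MeasurementSet({signal: times}, {signal: values}, frozenset(mask))


class TestOutputErrorE1:
    def test_perfect_prediction_is_zero(self, noise):
        t = np.array([0.0, 5.0, 10.0])
        ms = _single_signal_set("map", t, np.array([90.0, 80.0, 70.0]), {"map"})
        preds = [{"map": ms.values["map"].copy()}]
        assert output_error_e1(preds, [ms], noise) == 0.0

    def test_single_signal_reduces_to_rmse_over_sigma(self, noise):
        t = np.arange(4.0)
        data = np.full(4, 60.0)
        ms = _single_signal_set("map", t, data, {"map"})
        preds = [{"map": data + 5.0}]  # every error 5 mmHg, sigma 5
        assert output_error_e1(preds, [ms], noise) == pytest.approx(1.0, abs=1e-12)

    def test_mean_over_subjects(self):
        nm = NoiseModel(sigma_map=1.0)
        t = np.array([0.0])
        subjects, preds = [], []
        for err in (1.0, 3.0):  # per-subject normalized RMSE 1 and 3
            ms = _single_signal_set("map", t, np.array([50.0]), {"map"})
            subjects.append(ms)
            preds.append({"map": np.array([50.0 + err])})
        assert output_error_e1(preds, subjects, nm) == pytest.approx(2.0, abs=1e-12)

    def test_empty_mask_rejected(self, noise):
        t = np.array([0.0])
        ms = MeasurementSet({"map": t}, {"map": np.array([50.0])}, frozenset())
        with pytest.raises(ValueError):
            output_error_e1([{"map": np.array([50.0])}], [ms], noise)


class TestStateErrorE2:
    def _case3_set(self, n, bv, co, map_):
        t = np.arange(float(n))
        return MeasurementSet(
            {"bv": t, "co": t, "map": t}, {"bv": bv, "co": co, "map": map_},
            frozenset({"map"}),
        )

    def test_perfect_internal_states_zero(self, noise):
        ms = self._case3_set(3, np.ones(3), np.ones(3), np.ones(3))
        preds = [{s: ms.values[s].copy() for s in ("bv", "co", "map")}]
        assert state_error_e2(preds, [ms], noise) == 0.0

    def test_sigma_sized_errors_normalize_to_one(self, noise):
        ms = self._case3_set(4, np.full(4, 2.0), np.full(4, 4.0), np.full(4, 80.0))
        preds = [{
            "bv": ms.values["bv"] + noise.sigma_bv,
            "co": ms.values["co"] - noise.sigma_co,
            "map": ms.values["map"],
        }]
        assert state_error_e2(preds, [ms], noise) == pytest.approx(1.0, abs=1e-12)

    def test_two_sample_pooled_root(self):
        # errors (sigma, 2*sigma) pooled inside one root: sqrt(5/2)
        nm = NoiseModel(sigma_bv=0.2, sigma_co=0.3, sigma_map=5.0)
        t = np.array([0.0, 1.0])
        ms = MeasurementSet({"bv": t, "map": t},
                            {"bv": np.zeros(2) + 2.0, "map": np.full(2, 70.0)},
                            frozenset({"map"}))
        preds = [{"bv": ms.values["bv"] + np.array([0.2, 0.4]), "map": ms.values["map"]}]
        assert state_error_e2(preds, [ms], nm) == pytest.approx(np.sqrt(2.5), abs=1e-12)

    def test_case1_returns_defined_empty(self, noise):
        t = np.array([0.0])
        ms = MeasurementSet(
            {"bv": t, "co": t, "map": t},
            {"bv": np.array([2.0]), "co": np.array([4.0]), "map": np.array([90.0])},
            frozenset({"bv", "co", "map"}),
        )
        preds = [{s: ms.values[s] for s in ("bv", "co", "map")}]
        assert state_error_e2(preds, [ms], noise) is None

    def test_unit_rescaling_invariance(self):
        # jointly rescaling a signal's units and its sigma leaves e2 unchanged
        t = np.arange(3.0)
        bv = np.array([2.0, 1.8, 1.9])
        err = np.array([0.05, -0.1, 0.2])
        ms = MeasurementSet({"bv": t, "map": t}, {"bv": bv, "map": np.full(3, 70.0)},
                            frozenset({"map"}))
        ms_ml = MeasurementSet({"bv": t, "map": t},
                               {"bv": bv * 1000, "map": np.full(3, 70.0)},
                               frozenset({"map"}))
        e_l = state_error_e2([{"bv": bv + err, "map": ms.values["map"]}], [ms],
                             NoiseModel(sigma_bv=0.1))
        e_ml = state_error_e2([{"bv": (bv + err) * 1000, "map": ms.values["map"]}], [ms_ml],
                              NoiseModel(sigma_bv=100.0))
        assert e_l == pytest.approx(e_ml, rel=1e-12)


class TestDeviationDistance:
    def test_zero_at_mode_and_identity_with_j2(self, mode_params, bounds):
        prior = Prior(mode_params, bounds, lam=0.7)
        assert deviation_distance(mode_params, prior) == 0.0
        theta = mode_params.replace(K_p=mode_params.K_p + 0.1 * bounds.ranges[2])
        d = deviation_distance(theta, prior)
        from hemovol import regularizer_j2

        assert prior.lam * d == pytest.approx(regularizer_j2(theta, prior), rel=1e-14)

    def test_bound_to_bound_contribution_is_one(self, bounds, mode_params):
        low = mode_params.replace(MAP_target=bounds.lower[-1])
        high = low.replace(MAP_target=bounds.upper[-1])
        prior = Prior(low, bounds, lam=0.0)
        dev = normalized_deviations(high, prior)
        assert dev[-1] == pytest.approx(1.0, abs=1e-14)
        assert deviation_distance(high, prior) == pytest.approx(1.0, abs=1e-14)


class TestSignedRank:
    def test_uniform_signs_match_exact_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.3, 0.5, 0.1, 0.2, 0.4])
        p, degenerate = paired_signed_rank_bonferroni(a, b)
        assert not degenerate
        assert p == pytest.approx(2 / 2**5, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        # independent oracle: enumerate all sign assignments of |d| ranks
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, size=8)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stats = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=len(d))
        ]
        w_low = min(w_obs, total - w_obs)
        p_exact = np.mean([min(w, total - w) <= w_low for w in stats])
        p, _ = paired_signed_rank_bonferroni(d, np.zeros_like(d))
        assert p == pytest.approx(p_exact, rel=1e-12)

    def test_bonferroni_scaling_and_cap(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - 1.0
        p1, _ = paired_signed_rank_bonferroni(a, b, n_comparisons=1)
        p3, _ = paired_signed_rank_bonferroni(a, b, n_comparisons=3)
        assert p3 == pytest.approx(min(1.0, 3 * p1), abs=1e-12)
        p_many, _ = paired_signed_rank_bonferroni(a, b, n_comparisons=1000)
        assert p_many == 1.0

    def test_antisymmetric_in_pair_order(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert paired_signed_rank_bonferroni(a, b) == paired_signed_rank_bonferroni(b, a)

    def test_all_zero_differences_degenerate(self):
        a = np.ones(6)
        p, degenerate = paired_signed_rank_bonferroni(a, a)
        assert p == 1.0 and degenerate
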