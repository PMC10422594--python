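"""Warping, segment costs, template updates, DP optimality, convergence."""
import numpy as np
import pytest

import radarhrv as rh
from radarhrv.config import OptimizerParams
from radarhrv.enhance import AccelSignal, Segmentation
from radarhrv.segmentation import Template, total_cost


class TestWarp:
    def test_identity(self):
        x = np.random.default_rng(0).standard_normal(17)
        np.testing.assert_array_equal(rh.warp(x, 17), x)

    def test_linear_ramp_exact(self):
        ramp = np.linspace(2.0, 5.0, 10)
        np.testing.assert_allclose(rh.warp(ramp, 5), np.linspace(2.0, 5.0, 5), atol=1e-12)

    def test_smooth_round_trip(self):
        # oracle: closed-form sinusoid up-down round trip
        x = np.sin(np.linspace(0, 2 * np.pi, 40))
        back = rh.warp(rh.warp(x, 80), 40)
        assert np.max(np.abs(back - x)) < 1e-6

    @pytest.mark.parametrize("p", [1, 3])
    def test_too_short_target_rejected(self, p):
        with pytest.raises(ValueError):
            rh.warp(np.zeros(10), p)


class TestSegmentCost:
    def test_zero_for_warped_template(self):
        mu = Template(np.sin(np.linspace(0, np.pi, 20)))
        seg = rh.warp(mu.values, 33)
        assert rh.segment_cost(seg, mu) == 0.0

    def test_unit_impulse_perturbation_costs_one(self):
        mu = Template(np.cos(np.linspace(0, 1, 15)))
        seg = rh.warp(mu.values, 25)
        seg[7] += 1.0
        assert rh.segment_cost(seg, mu) == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        mu = Template(rng.standard_normal(12))
        for _ in range(5):
            assert rh.segment_cost(rng.standard_normal(19), mu) >= 0

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            rh.segment_cost(np.zeros(3), Template(np.zeros(8)))


class TestUpdateTemplate:
    def test_identical_segments_reproduce_themselves(self):
        seg = np.sin(np.linspace(0, 2, 20))
        x = np.concatenate([[0.0], seg, seg, seg])
        a = AccelSignal(x, 250.0)
        s = Segmentation(np.array([0, 20, 40, 60]), 250.0)
        mu = rh.update_template(a, s, 20)
        np.testing.assert_allclose(mu.values, seg, atol=1e-12)

    def test_two_equal_length_segments_average(self):
        rng = np.random.default_rng(1)
        u, v = rng.standard_normal((2, 15))
        x = np.concatenate([[0.0], u, v])
        a = AccelSignal(x, 250.0)
        s = Segmentation(np.array([0, 15, 30]), 250.0)
        mu = rh.update_template(a, s, 15)
        np.testing.assert_allclose(mu.values, (u + v) / 2, atol=1e-12)

    def test_unequal_lengths_match_hand_weighted_average(self):
        # oracle: independent arithmetic with warp
        rng = np.random.default_rng(2)
        segs = [rng.standard_normal(n) for n in (10, 14, 19)]
        x = np.concatenate([[0.0], *segs])
        cut = np.array([0, 10, 24, 43])
        a = AccelSignal(x, 250.0)
        m = 12
        mu = rh.update_template(a, Segmentation(cut, 250.0), m)
        expected = sum(len(s) * rh.warp(s, m) for s in segs) / 43
        np.testing.assert_allclose(mu.values, expected, atol=1e-9)

    def test_short_segment_rejected(self):
        a = AccelSignal(np.zeros(20), 250.0)
        with pytest.raises(ValueError):
            rh.update_template(a, Segmentation(np.array([0, 2, 10]), 250.0), 8)


def _params(b_samples, fs=250.0, **kw):
    return OptimizerParams(neighborhood_b_ms=b_samples * 1e3 / fs, **kw)


class TestDPUpdate:
    def test_recovers_truth_with_known_template(self, tiled_instance):
        accel, truth, base = tiled_instance
        m = int(np.median(np.diff(truth.cutoffs)))
        mu = Template(rh.warp(base.values, m))
        rng = np.random.default_rng(8)
        perturb = rng.integers(-3, 4, len(truth.cutoffs))
        s0 = Segmentation(truth.cutoffs + perturb, accel.fs)
        res = rh.dp_update_segmentation(accel, mu, s0, _params(5))
        np.testing.assert_array_equal(res.segmentation.cutoffs, truth.cutoffs)

    def test_singleton_neighborhood_returns_input(self, tiled_instance):
        accel, truth, base = tiled_instance
        mu = Template(rh.warp(base.values, 30))
        res = rh.dp_update_segmentation(accel, mu, truth, _params(0))
        np.testing.assert_array_equal(res.segmentation.cutoffs, truth.cutoffs)

    def test_matches_exhaustive_on_random_instances(self):
        from radarhrv.benchmarks import dp_oracle_batch

        assert dp_oracle_batch(25, seed=5)["agreement_rate"] == 1.0

    def test_output_within_neighborhood(self, tiled_instance):
        accel, truth, base = tiled_instance
        mu = Template(rh.warp(base.values, 30))
        rng = np.random.default_rng(9)
        s0 = Segmentation(truth.cutoffs + rng.integers(-4, 5, len(truth.cutoffs)), accel.fs)
        res = rh.dp_update_segmentation(accel, mu, s0, _params(5))
        assert np.all(np.abs(res.segmentation.cutoffs - s0.cutoffs) <= 5)

    def test_overlapping_neighborhoods_rejected(self):
        a = AccelSignal(np.random.default_rng(0).standard_normal(40), 250.0)
        s = Segmentation(np.array([5, 12, 19]), 250.0)
        mu = Template(np.zeros(6))
        with pytest.raises(ValueError, match="educe"):
            rh.dp_update_segmentation(a, mu, s, _params(4))

    def test_never_increases_objective(self, tiled_instance):
        accel, truth, base = tiled_instance
        rng = np.random.default_rng(10)
        s0 = Segmentation(truth.cutoffs + rng.integers(-4, 5, len(truth.cutoffs)), accel.fs)
        mu = rh.update_template(accel, s0, 30)
        before = total_cost(accel, s0, mu)
        res = rh.dp_update_segmentation(accel, mu, s0, _params(5))
        assert res.cost <= before + 1e-12


class TestExhaustiveOracle:
    def test_single_interior_cut_matches_direct_scan(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        a = AccelSignal(x, 250.0)
        mu = Template(rng.standard_normal(10))
        s = Segmentation(np.array([10, 30, 50]), 250.0)
        res = rh.exhaustive_oracle(a, mu, s, _params(3))
        best = None
        for c0 in range(7, 14):
            for c1 in range(27, 34):
                for c2 in range(47, 54):
                    cost = rh.segment_cost(x[c0 + 1 : c1 + 1], mu) + rh.segment_cost(
                        x[c1 + 1 : c2 + 1], mu
                    )
                    if best is None or cost < best[0]:
                        best = (cost, (c0, c1, c2))
        assert tuple(res.segmentation.cutoffs) == best[1]
        assert res.cost == pytest.approx(best[0], rel=1e-12)

    def test_search_space_limit(self):
        a = AccelSignal(np.zeros(5000), 250.0)
        s = Segmentation(np.arange(0, 5000, 200), 250.0)
        mu = Template(np.zeros(10))
        with pytest.raises(ValueError, match="search space"):
            rh.exhaustive_oracle(a, mu, s, _params(5))


class TestHasConverged:
    def _seg(self, cutoffs):
        return Segmentation(np.asarray(cutoffs), 250.0)

    def test_identical_segmentations(self):
        s = self._seg(np.arange(0, 1000, 200))
        conv, frac = rh.has_converged(s, s, OptimizerParams())
        assert conv and frac == 1.0

    def test_threshold_is_inclusive_at_eighty_percent(self):
        base = np.arange(0, 2000, 200)
        moved = base.copy()
        moved[:2] += 10  # 40 ms > alpha1
        conv, frac = rh.has_converged(self._seg(base), self._seg(moved), OptimizerParams())
        assert frac == pytest.approx(0.8)
        assert conv

    def test_below_threshold_not_converged(self):
        base = np.arange(0, 2000, 200)
        moved = base.copy()
        moved[:3] += 10
        conv, frac = rh.has_converged(self._seg(base), self._seg(moved), OptimizerParams())
        assert frac == pytest.approx(0.7)
        assert not conv

    def test_one_sample_at_250hz_is_stable(self):
        base = np.arange(0, 2000, 200)
        conv, frac = rh.has_converged(
            self._seg(base), self._seg(base + 1), OptimizerParams()
        )
        assert frac == 1.0 and conv

    def test_cardinality_mismatch_is_internal_error(self):
        with pytest.raises(RuntimeError):
            rh.has_converged(
                self._seg([0, 200, 400]), self._seg([0, 200]), OptimizerParams()
            )


class TestJointOptimization:
    def test_balanced_perturbation_recovers_truth_quickly(self):
        from radarhrv.pipeline import make_tiled_instance

        for seed in (0, 1, 2):
            accel, truth, _ = make_tiled_instance(seed)
            k = len(truth.cutoffs)
            perturb = np.array([3 if j % 2 == 0 else -3 for j in range(k)])
            s0 = Segmentation(truth.cutoffs + perturb, accel.fs)
            res = rh.run_joint_optimization(accel, s0, _params(5))
            assert res.converged and res.iterations <= 3
            np.testing.assert_array_equal(res.segmentation.cutoffs, truth.cutoffs)

    def test_random_perturbation_recovers_all_intervals(self):
        # absolute positions are only defined up to a global shift (the
        # objective is translation-degenerate); the intervals must match
        from radarhrv.pipeline import make_tiled_instance

        hits = 0
        for seed in range(10):
            accel, truth, _ = make_tiled_instance(seed)
            rng = np.random.default_rng(100 + seed)
            s0 = Segmentation(
                truth.cutoffs + rng.integers(-3, 4, len(truth.cutoffs)), accel.fs
            )
            res = rh.run_joint_optimization(accel, s0, _params(5))
            gap_err = np.abs(np.diff(res.segmentation.cutoffs) - np.diff(truth.cutoffs))
            hits += int(np.max(gap_err) <= 1)
        assert hits >= 8

    def test_already_optimal_converges_in_one_iteration(self, tiled_instance):
        accel, truth, _ = tiled_instance
        res = rh.run_joint_optimization(accel, truth, _params(5))
        assert res.converged and res.iterations == 1
        np.testing.assert_array_equal(res.segmentation.cutoffs, truth.cutoffs)

    def test_objective_nonincreasing_at_each_dp_step(self):
        fx = rh.make_fixture("harmonic-confound", seed=5, duration_s=20.0)
        a = rh.second_difference(fx["phase"])
        p = rh.short_time_power(a)
        s0 = rh.initial_cutpoints(p)
        res = rh.run_joint_optimization(a, s0, OptimizerParams())
        for entry in res.trace:
            assert entry["objective_after"] <= entry["objective_before"] + 1e-9

    def test_nonconvergence_warns_and_returns_last(self, tiled_instance):
        accel, truth, _ = tiled_instance
        rng = np.random.default_rng(3)
        s0 = Segmentation(truth.cutoffs + rng.integers(-4, 5, len(truth.cutoffs)), accel.fs)
        params = OptimizerParams(max_iterations=1, alpha2=1.0, alpha1_ms=0.0,
                                 neighborhood_b_ms=20.0)
        with pytest.warns(RuntimeWarning, match="converge"):
            res = rh.run_joint_optimization(accel, s0, params)
        assert not res.converged
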