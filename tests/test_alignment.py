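import numpy as np
import pytest
from scipy.signal.windows import hamming

from tasc.alignment import (
    alignment_loss,
    build_weights,
    grid_align,
    linear_align,
    penalty,
    warp_sequence,
    warped_length,
    weighted_euclidean,
)
from tasc.segments import AlignmentParams

IDENTITY = AlignmentParams(0.0, 1.0)


def smooth_sequence(rng, n_features, length):
    t = np.linspace(0, 1, length)
    return np.array(
        [
            np.sin(2 * np.pi * rng.uniform(0.5, 2.5) * t + rng.uniform(0, 2 * np.pi))
            for _ in range(n_features)
        ]
    )


class TestBuildWeights:
    def test_equal_lengths_no_tail(self):
        dw = build_weights(5, 5)
        np.testing.assert_allclose(dw.weights, 1.0 + hamming(5, sym=True))

    def test_unequal_lengths_unit_tail(self):
        dw = build_weights(3, 7)
        assert len(dw.weights) == 7
        np.testing.assert_allclose(dw.weights[3:], 1.0)
        np.testing.assert_allclose(dw.weights[:3], 1.0 + hamming(3, sym=True))

    def test_peak_at_center_for_odd_minlen(self):
        dw = build_weights(9, 15)
        assert int(np.argmax(dw.weights)) == 4


class TestWeightedEuclidean:
    def test_identity_is_zero_and_symmetric(self, rng):
        x = rng.normal(size=(3, 20))
        y = rng.normal(size=(3, 20))
        assert weighted_euclidean(x, x) == 0.0
        assert weighted_euclidean(x, y) == pytest.approx(weighted_euclidean(y, x))

    def test_single_center_frame_difference(self):
        x = np.zeros((1, 9))
        y = np.zeros((1, 9))
        delta = 0.37
        y[0, 4] = delta
        w = 1.0 + hamming(9, sym=True)
        assert weighted_euclidean(x, y) == pytest.approx(np.sqrt(w[4]) * delta)

    def test_feature_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_euclidean(np.zeros((2, 5)), np.zeros((3, 5)))

    def test_positive_for_different_lengths(self, rng):
        x = rng.normal(size=(2, 10))
        assert weighted_euclidean(x, x[:, :7]) > 0


class TestWarpSequence:
    def test_identity_returns_input(self, rng):
        x = rng.normal(size=(3, 40))
        out = warp_sequence(x, IDENTITY, 40, 40)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_offset_moves_spike(self):
        x = np.zeros((1, 100))
        x[0, 50] = 1.0
        # tau = -0.1 in the normalized domain shifts content 10 frames later
        out = warp_sequence(x, AlignmentParams(-0.1, 1.0), 100, 100)
        assert abs(int(np.argmax(out[0])) - 60) <= 1

    def test_double_slope_on_ramp(self):
        x = np.arange(50, dtype=float)[None, :]
        out = warp_sequence(x, AlignmentParams(0.0, 2.0), 50, 50)
        # first half reads the ramp at double speed before clamping
        diffs = np.diff(out[0])[:20]
        np.testing.assert_allclose(diffs, 2.0, atol=1e-9)

    def test_out_of_range_clamps(self):
        x = np.array([[1.0, 2.0, 3.0]])
        out = warp_sequence(x, AlignmentParams(-5.0, 1.0), 4, 3)
        np.testing.assert_allclose(out, 1.0)  # clamped to first frame

    def test_warped_length_rule(self):
        assert warped_length(90, 0.8) in (112, 113)
        assert warped_length(90, 1.0) == 90
        assert warped_length(4, 10.0) == 2  # floor at 2 frames


class TestPenalty:
    def test_closed_forms(self):
        assert penalty(AlignmentParams(0.0, 1.0)) == 0.0
        assert penalty(AlignmentParams(1.0, 1.0)) == pytest.approx(np.pi / 4)
        assert penalty(AlignmentParams(0.0, 2.0)) == pytest.approx(1.5 * np.pi / 4)

    def test_positive_away_from_identity(self, rng):
        for _ in range(20):
            tau = rng.uniform(-1, 1)
            s = rng.uniform(0.2, 3.0)
            if (tau, s) != (0.0, 1.0):
                assert penalty(AlignmentParams(tau, s)) > 0


class TestAlignmentLoss:
    def test_alpha_zero_is_pure_distance(self, rng):
        q = rng.normal(size=(2, 30))
        tpl = rng.normal(size=(2, 30))
        params = AlignmentParams(0.05, 1.1)
        warped = warp_sequence(q, params, 30, 30)
        assert alignment_loss(q, tpl, params, alpha=0.0) == pytest.approx(
            weighted_euclidean(warped, tpl)
        )

    def test_identity_on_self_is_zero_for_any_alpha(self, rng):
        q = rng.normal(size=(2, 25))
        for alpha in (0.0, 1.0, 10.0):
            assert alignment_loss(q, q, IDENTITY, alpha) == pytest.approx(0.0, abs=1e-9)

    def test_loss_linear_in_alpha(self, rng):
        q = rng.normal(size=(1, 20))
        tpl = rng.normal(size=(1, 20))
        params = AlignmentParams(0.1, 1.2)
        l0 = alignment_loss(q, tpl, params, 0.0)
        l1 = alignment_loss(q, tpl, params, 1.0)
        l2 = alignment_loss(q, tpl, params, 2.0)
        assert l2 - l1 == pytest.approx(l1 - l0)
        assert l1 > l0


class TestLinearAlign:
    def test_self_alignment_recovers_identity(self, rng):
        q = smooth_sequence(rng, 3, 60)
        p = linear_align(q, q, alpha=0.0)
        assert abs(p.tau_w) < 1e-3 and abs(p.s_w - 1.0) < 2e-3
        assert p.cost < 1e-4

    def test_recovers_generating_warp(self, rng):
        # aligning a motif onto its warped variant recovers the draw
        for _ in range(5):
            L = int(rng.integers(60, 91))
            q = smooth_sequence(rng, 5, L)
            tau, s = rng.uniform(-0.1, 0.1), rng.uniform(0.8, 1.2)
            tpl = warp_sequence(q, AlignmentParams(tau, s), warped_length(L, s), L)
            p = linear_align(q, tpl, alpha=0.0)
            assert abs(p.tau_w - tau) < 0.01
            assert abs(p.s_w - s) < 0.02

    def test_large_alpha_pulls_to_identity(self, rng):
        q = smooth_sequence(rng, 2, 40)
        tpl = smooth_sequence(rng, 2, 40)
        p = linear_align(q, tpl, alpha=1e6)
        assert abs(p.tau_w) < 0.01 and abs(p.s_w - 1.0) < 0.01

    def test_never_worse_than_identity(self, rng):
        for _ in range(10):
            q = rng.normal(size=(2, 30))
            tpl = rng.normal(size=(2, 35))
            alpha = float(rng.uniform(0, 2))
            p = linear_align(q, tpl, alpha=alpha)
            assert p.cost <= alignment_loss(q, tpl, IDENTITY, alpha) + 1e-9

    def test_cost_equals_loss_at_returned_params(self, rng):
        q = smooth_sequence(rng, 2, 45)
        tpl = smooth_sequence(rng, 2, 50)
        p = linear_align(q, tpl, alpha=0.5)
        assert p.cost == pytest.approx(alignment_loss(q, tpl, p, 0.5), abs=1e-9)

    def test_agrees_with_shgo(self, rng):
        q = smooth_sequence(rng, 2, 40)
        tau, s = 0.06, 0.9
        tpl = warp_sequence(q, AlignmentParams(tau, s), warped_length(40, s), 40)
        p_fast = linear_align(q, tpl, alpha=0.1)
        p_shgo = linear_align(q, tpl, alpha=0.1, method="shgo")
        assert abs(p_fast.tau_w - p_shgo.tau_w) < 0.01
        assert abs(p_fast.s_w - p_shgo.s_w) < 0.01

    def test_invalid_bounds_raise(self, rng):
        q = rng.normal(size=(1, 10))
        with pytest.raises(ValueError):
            linear_align(q, q, s_bounds=(-1.0, 2.0))
        with pytest.raises(ValueError):
            linear_align(q, q, tau_bounds=(0.3, 0.1))


class TestGridAlign:
    def test_matches_default_on_small_instance(self, rng):
        q = smooth_sequence(rng, 2, 25)
        tau, s = -0.0437, 1.1531  # deliberately off the oracle's grid points
        tpl = warp_sequence(q, AlignmentParams(tau, s), warped_length(25, s), 25)
        g = grid_align(q, tpl, alpha=0.0, resolution=0.01)
        p = linear_align(q, tpl, alpha=0.0)
        assert abs(g.tau_w - p.tau_w) <= 0.011
        assert abs(g.s_w - p.s_w) <= 0.011
        assert p.cost <= g.cost + 1e-6
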