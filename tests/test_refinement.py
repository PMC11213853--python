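import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tasc
from tasc.alignment import weighted_euclidean
from tasc.config import semi_synthetic_config
from tasc.refinement import (
    TASCConfig,
    compute_centroid,
    costs_to_scores,
    generate_variants,
    remove_outliers,
    run_epoch,
    select_nonoverlapping,
    semi_synthetic_schedules,
)
from tasc.segments import Segment


def brute_force_max_score(candidates):
    """Exhaustive weighted-interval-scheduling optimum (oracle)."""
    best = 0.0
    n = len(candidates)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            ivs = [candidates[i][0] for i in combo]
            ok = all(
                a[1] <= b[0] or b[1] <= a[0]
                for a, b in itertools.combinations(ivs, 2)
            )
            if ok:
                best = max(best, sum(candidates[i][1] for i in combo))
    return best


class TestSelectNonoverlapping:
    def test_disjoint_input_all_selected(self):
        cands = [((0, 5), 0.1), ((10, 15), 0.9), ((20, 30), 0.5)]
        assert select_nonoverlapping(cands) == [0, 1, 2]

    def test_higher_score_wins_on_overlap(self):
        cands = [((0, 10), 0.5), ((5, 15), 0.9)]
        assert select_nonoverlapping(cands) == [1]

    def test_three_interval_example(self):
        cands = [((0, 10), 1.0), ((5, 15), 1.0), ((12, 20), 0.8)]
        picked = select_nonoverlapping(cands)
        total = sum(cands[i][1] for i in picked)
        assert total == pytest.approx(1.8)
        assert picked == [0, 2]

    def test_nonfinite_scores_ignored(self):
        cands = [((0, 10), -np.inf), ((0, 10), 0.3)]
        assert select_nonoverlapping(cands) == [1]

    def test_empty(self):
        assert select_nonoverlapping([]) == []

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_optimum(self, data):
        n = data.draw(st.integers(1, 9))
        cands = []
        for _ in range(n):
            a = data.draw(st.integers(0, 40))
            ln = data.draw(st.integers(1, 15))
            sc = data.draw(st.floats(0, 1, allow_nan=False, width=32))
            cands.append(((a, a + ln), float(sc)))
        picked = select_nonoverlapping(cands)
        ivs = [cands[i][0] for i in picked]
        assert all(
            a[1] <= b[0] or b[1] <= a[0]
            for a, b in itertools.combinations(ivs, 2)
        )
        total = sum(cands[i][1] for i in picked)
        assert total == pytest.approx(brute_force_max_score(cands))


class TestCostsToScores:
    def test_single_cluster_example(self):
        np.testing.assert_allclose(costs_to_scores([0.2, 0.4], [0, 0]), [0.5, 0.0])

    def test_all_zero_costs(self):
        np.testing.assert_allclose(costs_to_scores([0.0, 0.0], [0, 0]), [1.0, 1.0])

    def test_per_cluster_scale_invariance(self, rng):
        costs = rng.uniform(0.1, 5.0, 10)
        clusters = np.array([0] * 5 + [1] * 5)
        base = costs_to_scores(costs, clusters)
        scaled = costs.copy()
        scaled[5:] *= 13.0  # rescaling one cluster leaves all scores unchanged
        np.testing.assert_allclose(costs_to_scores(scaled, clusters), base)

    def test_scores_in_unit_interval_and_monotone(self, rng):
        costs = np.sort(rng.uniform(0, 3, 8))
        scores = costs_to_scores(costs, np.zeros(8, int))
        assert np.all((scores >= 0) & (scores <= 1))
        assert np.all(np.diff(scores) <= 1e-12)  # lower cost -> higher score
        assert scores[-1] == 0.0


class TestRemoveOutliers:
    def test_distant_member_removed(self, rng):
        base = rng.normal(size=(2, 20))
        members = [base + rng.normal(scale=0.01, size=base.shape) for _ in range(9)]
        members.append(base + 50.0)
        kept, removed, mean_d, std_d = remove_outliers(members, gamma=1.0)
        assert removed == [9]
        assert len(kept) == 9
        # statistics are computed before removal
        dists = [
            np.mean([weighted_euclidean(members[i], members[j]) for j in range(10) if j != i])
            for i in range(10)
        ]
        assert mean_d == pytest.approx(np.mean(dists))

    def test_gamma_infinity_removes_nothing(self, rng):
        members = [rng.normal(size=(2, 15)) for _ in range(6)]
        kept, removed, *_ = remove_outliers(members, gamma=1e12)
        assert removed == [] and len(kept) == 6

    def test_small_cluster_passthrough(self, rng):
        one = [rng.normal(size=(2, 10))]
        assert remove_outliers(one, 2.0)[0] == [0]


class TestComputeCentroid:
    def test_single_member_returned(self, rng):
        m = rng.normal(size=(3, 12))
        np.testing.assert_allclose(compute_centroid([m], "median", True), m)

    def test_elementwise_median(self):
        members = [np.full((1, 4), v) for v in (1.0, 2.0, 10.0)]
        out = compute_centroid(members, "median", existing=False)
        np.testing.assert_allclose(out, np.full((1, 4), 2.0))

    def test_existing_returns_actual_member(self, rng):
        members = [rng.normal(size=(2, 10)) for _ in range(5)]
        out = compute_centroid(members, "median", existing=True)
        assert any(np.array_equal(out, m) for m in members)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            compute_centroid([], "median")


class TestGenerateVariants:
    def test_grid_size_inclusive_ranges(self):
        grid = generate_variants(Segment(100, 190), (-10, 10), (-1, 10), T=1000)
        assert grid.starts.shape == (21, 12)
        assert grid.valid.all()

    def test_single_variant_identity(self):
        grid = generate_variants(Segment(10, 20), (0, 0), (0, 0), T=100)
        assert grid.starts.shape == (1, 1)
        assert (grid.starts[0, 0], grid.ends[0, 0]) == (10, 20)

    def test_boundary_clipping_marks_invalid(self):
        grid = generate_variants(Segment(3, 23), (-10, 0), (0, 0), T=100)
        # offsets -10..-4 would start before frame 0
        assert (~grid.valid[:7, 0]).all()
        assert grid.valid[7:, 0].all()
        assert np.isneginf(grid.scores[~grid.valid]).all()


class TestSchedulesAndConfig:
    def test_semi_synthetic_schedules(self):
        L, alpha = semi_synthetic_schedules(10)
        assert L(1) == (-1, 10) and L(7) == (-7, 10)
        assert alpha[0] == pytest.approx(10**0.5)
        assert alpha[-1] == pytest.approx(10**-1)
        R = np.log10(alpha)
        np.testing.assert_allclose(np.diff(R), np.diff(R)[0])

    def test_alpha_and_L_accept_scalars_and_arrays(self):
        c = TASCConfig(L=(-2, 5), alpha=[1.2, 1.0, 0.8, 0.6])
        assert c.L_at(3) == (-2, 5)
        assert c.alpha_at(2) == 1.0
        assert c.alpha_at(99) == 0.6  # clamped to last entry

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TASCConfig(M=(5, -5))
        with pytest.raises(ValueError):
            TASCConfig(gamma=0.0)


@pytest.fixture(scope="module")
def small_dataset():
    lib = tasc.make_motif_library(3, length_range=(40, 60), n_features=3, seed=5)
    return tasc.assemble_signal(lib, n_variants_per_motif=5, noise_sigma=0.01, seed=6)


class TestEpochLoop:
    def test_epoch_outputs_nonoverlapping_inrange(self, small_dataset):
        ds = small_dataset
        cfg = semi_synthetic_config(
            epochs=2, window=50, stride=10, n_clusters=3, m_step=2, l_step=2, seed=0
        )
        res = tasc.run_tasc(ds.signal, cfg, truth=ds.truth)
        segs = sorted(res.state.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start
        assert segs[0].start >= 0 and segs[-1].end <= ds.signal.n_frames
        # labels refer to live clusters, stored costs match stored params
        labels = {s.label for s in segs}
        assert labels <= set(range(len(labels) + 5))

    def test_zero_epochs_returns_initialization(self, small_dataset):
        ds = small_dataset
        cfg = semi_synthetic_config(epochs=0, window=50, stride=10, n_clusters=3, seed=0)
        res = tasc.run_tasc(ds.signal, cfg)
        assert res.metrics[-1]["epoch"] == 0
        assert res.state is res.initial_state

    def test_determinism_end_to_end(self, small_dataset):
        ds = small_dataset
        cfg = semi_synthetic_config(
            epochs=2, window=50, stride=10, n_clusters=3, m_step=2, l_step=2, seed=3
        )
        r1 = tasc.run_tasc(ds.signal, cfg, truth=ds.truth)
        r2 = tasc.run_tasc(ds.signal, cfg, truth=ds.truth)
        assert [s.interval() for s in r1.state.segments] == [
            s.interval() for s in r2.state.segments
        ]
        assert [s.label for s in r1.state.segments] == [s.label for s in r2.state.segments]
        assert r1.metrics == r2.metrics

    def test_external_init_validated(self, small_dataset):
        ds = small_dataset
        cfg = semi_synthetic_config(epochs=1, n_clusters=3, seed=0)
        bad = [Segment(0, ds.signal.n_frames + 50, label=0)]
        with pytest.raises(ValueError, match="outside"):
            tasc.run_tasc(ds.signal, cfg, init=bad)
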