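"""The iterative refinement loop coupling segmentation and clustering.

Each epoch walks the alternating-step procedure:

1. drop cluster members whose mean within-cluster distance exceeds
   ``mean + gamma * std`` of the per-member means (outlier removal);
2. compute a centroid sequence per cluster (element-wise median by
   default, optionally the closest actual member);
3. for every surviving segment, enumerate its temporal neighbors — start
   offset ``m`` in M, length change ``l`` in L — and score each variant by
   linearly aligning it to its cluster's centroid with penalty weight
   ``alpha``;
4. convert per-cluster alignment costs to scores in [0, 1] and select the
   score-maximal set of pairwise non-overlapping variants (weighted
   interval scheduling);
5. warp the selected segments with their fitted parameters, resample to
   the mean selected length, re-embed and re-cluster;
6. scan the remaining large gaps for windows close enough to some
   centroid and reinstate them;
7. repeat until the configured epoch count or until boundaries stop
   moving.

The schedules L(n) and alpha(n) may vary per epoch: typically the length
search range widens and the warp penalty relaxes as segmentation
stabilizes, permitting progressively stronger warps for fine-tuning.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from . import evaluation
from .alignment import (
    DEFAULT_S_BOUNDS,
    DEFAULT_TAU_BOUNDS,
    linear_align,
    warp_sequence,
    weighted_euclidean,
)
from .embedding import (
    FuzzyCMeans,
    PCAEmbedder,
    cluster_segments,
    embed_segments,
    naive_segmentation,
    resample_sequence,
    spatiotemporal_dilution,
)
from .preprocess import (
    ContinuousSignal,
    detect_activity_periods,
    filter_valid_segments,
    normalize_signal,
    trim_segments_to_activity,
)
from .segments import AlignmentParams, Segment, assert_nonoverlapping

logger = logging.getLogger("tasc")

__all__ = [
    "TASCConfig",
    "ClusterState",
    "VariantGrid",
    "TASCState",
    "remove_outliers",
    "compute_centroid",
    "generate_variants",
    "score_variants",
    "costs_to_scores",
    "select_nonoverlapping",
    "reassign_gaps",
    "run_epoch",
    "run_tasc",
    "semi_synthetic_schedules",
]


# ---------------------------------------------------------------------------
# configuration


def semi_synthetic_schedules(epochs: int) -> tuple[Callable[[int], tuple[int, int]], list[float]]:
    """The worked semi-synthetic schedules: L(n) = (-n, 10), alpha = 10^R(n)
    with R evenly spaced from 0.5 down to -1 over the epochs."""
    R = np.linspace(0.5, -1.0, epochs)
    return (lambda n: (-n, 10)), [float(10.0**r) for r in R]


@dataclass
class TASCConfig:
    """All refinement parameters.

    ``M``/``L``: inclusive offset and length-change ranges for temporal
    neighbors (frames); ``L`` and ``alpha`` may be per-epoch (a list, or a
    callable of the 1-based epoch for ``L``).  ``gamma`` scales the
    outlier threshold in within-cluster distance standard deviations.
    ``m_step``/``l_step`` subsample the variant grid for speed.
    """

    M: tuple[int, int] = (-10, 10)
    L: tuple[int, int] | Sequence[tuple[int, int]] | Callable[[int], tuple[int, int]] = (-1, 10)
    alpha: float | Sequence[float] = 1.0
    gamma: float = 4.0
    centroid_method: str = "median"
    centroid_existing: bool = True
    epochs: int = 10
    window: int = 90
    stride: Optional[int] = None
    n_clusters: Optional[int] = 5
    k_range: Optional[tuple[int, int]] = None
    n_components: int | float = 10
    fuzziness: float = 2.0
    seed: int = 0
    outlier_center: str = "mean"
    # activity detection
    normalize: bool = True
    activity_cutoff_hz: float = 1.0
    activity_quantile: float = 0.25
    activity_min_frames: int = 5
    use_activity_filter: bool = True
    # optionally trim naive windows to the activity run they overlap most,
    # instead of merely validating them (rest-tail trimming); with tapered
    # motifs the trimmed boundaries inherit the energy detector's jitter,
    # which degrades the initial clustering, so validation is the default
    trim_initial: bool = False
    # dilution
    dilution: bool = False
    dilution_max_overlap: float = 0.5
    dilution_latent_radius: Optional[float] = None
    # variant grid subsampling
    m_step: int = 1
    l_step: int = 1
    # alignment search
    tau_bounds: tuple[float, float] = DEFAULT_TAU_BOUNDS
    s_bounds: tuple[float, float] = DEFAULT_S_BOUNDS
    align_method: str = "sampled"
    align_coarse: int = 16
    align_zoom_stages: int = 2
    align_n_basins: int = 1
    # gap reassignment: stride of the sliding search window as a fraction of
    # the mean segment length; fine enough that a recovered window's phase
    # error stays within the offset range M of the next epoch's variants
    gap_stride_fraction: float = 0.1
    # loop control
    refit_embedder: bool = True
    convergence_fraction: float = 0.01
    match_rule: str = "half_duration"

    def __post_init__(self) -> None:
        if self.M[0] > self.M[1]:
            raise ValueError("M range inverted")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    def L_at(self, epoch: int) -> tuple[int, int]:
        if callable(self.L):
            lo, hi = self.L(epoch)
        elif self.L and isinstance(self.L[0], (tuple, list)):
            lo, hi = self.L[min(epoch - 1, len(self.L) - 1)]
        else:
            lo, hi = self.L  # type: ignore[misc]
        if lo > hi:
            raise ValueError(f"L range inverted at epoch {epoch}: ({lo}, {hi})")
        return int(lo), int(hi)

    def alpha_at(self, epoch: int) -> float:
        if np.isscalar(self.alpha):
            a = float(self.alpha)  # type: ignore[arg-type]
        else:
            seq = list(self.alpha)  # type: ignore[arg-type]
            a = float(seq[min(epoch - 1, len(seq) - 1)])
        if a < 0:
            raise ValueError("alpha must be >= 0")
        return a

    def _align_kwargs(self) -> dict:
        return dict(
            tau_bounds=self.tau_bounds,
            s_bounds=self.s_bounds,
            method=self.align_method,
            coarse=self.align_coarse,
            zoom_stages=self.align_zoom_stages,
            n_basins=self.align_n_basins,
        )


# ---------------------------------------------------------------------------
# cluster statistics and centroids


@dataclass
class ClusterState:
    cluster_id: int
    member_ids: list[int]
    centroid: np.ndarray
    mean_pairwise_distance: float
    distance_std: float
    removed_ids: list[int] = field(default_factory=list)


def remove_outliers(
    members: list[np.ndarray],
    gamma: float,
    center: str = "mean",
) -> tuple[list[int], list[int], float, float]:
    """Flag members far from the rest of their cluster.

    Per-member mean weighted Euclidean distance to the other members is
    compared against ``center + gamma * std`` of those means (``center`` is
    their mean, or median when configured).  Returns (kept indices, removed
    indices, center distance, distance std) with statistics computed before
    any removal.  Clusters with fewer than 2 members pass through.
    """
    n = len(members)
    if n < 2:
        return list(range(n)), [], 0.0, 0.0
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = weighted_euclidean(members[i], members[j])
    per_member = dist.sum(axis=1) / (n - 1)
    mid = float(np.median(per_member)) if center == "median" else float(per_member.mean())
    std = float(per_member.std())
    threshold = mid + gamma * std
    kept = [i for i in range(n) if per_member[i] <= threshold]
    removed = [i for i in range(n) if per_member[i] > threshold]
    if not kept:  # pathological: keep the most central member
        best = int(np.argmin(per_member))
        kept, removed = [best], [i for i in range(n) if i != best]
    return kept, removed, mid, std


def compute_centroid(
    members: list[np.ndarray],
    method: str = "median",
    existing: bool = True,
) -> np.ndarray:
    """Cluster representative sequence.

    Members are resampled to their rounded mean length, combined
    element-wise by median (default) or mean; with ``existing`` the actual
    member closest to that average (weighted Euclidean) is returned
    instead, guaranteeing the centroid is a realizable sequence.
    """
    if not members:
        raise ValueError("empty cluster has no centroid")
    members = [np.atleast_2d(np.asarray(m, dtype=float)) for m in members]
    if len(members) == 1:
        return members[0].copy()
    target = max(2, int(round(np.mean([m.shape[1] for m in members]))))
    stack = np.stack([resample_sequence(m, target) for m in members])
    if method == "median":
        avg = np.median(stack, axis=0)
    elif method == "mean":
        avg = stack.mean(axis=0)
    else:
        raise ValueError(f"unknown centroid method {method!r}")
    if not existing:
        return avg
    dists = [weighted_euclidean(m, avg) for m in members]
    return members[int(np.argmin(dists))].copy()


# ---------------------------------------------------------------------------
# temporal-neighbor variants


@dataclass
class VariantGrid:
    """All (offset m, length change l) re-segmentations of one segment."""

    segment_id: int
    offsets: np.ndarray  # |M|
    length_deltas: np.ndarray  # |L|
    starts: np.ndarray  # |M| x |L|
    ends: np.ndarray
    valid: np.ndarray  # bool
    costs: np.ndarray  # inf where unscored/invalid
    scores: np.ndarray  # -inf where invalid
    params: np.ndarray  # object array of AlignmentParams or None


def generate_variants(
    segment: Segment,
    M: tuple[int, int],
    L: tuple[int, int],
    T: int,
    segment_id: int = 0,
    m_step: int = 1,
    l_step: int = 1,
) -> VariantGrid:
    """Enumerate intervals (start+m, end+m+l) over the inclusive ranges.

    Variants leaving [0, T) or shorter than 2 frames are marked invalid
    (score -inf) and never scored or selected.
    """
    offsets = np.arange(M[0], M[1] + 1, m_step)
    deltas = np.arange(L[0], L[1] + 1, l_step)
    mm, ll = np.meshgrid(offsets, deltas, indexing="ij")
    starts = segment.start + mm
    ends = segment.end + mm + ll
    valid = (starts >= 0) & (ends <= T) & (ends - starts >= 2)
    shape = starts.shape
    return VariantGrid(
        segment_id=segment_id,
        offsets=offsets,
        length_deltas=deltas,
        starts=starts,
        ends=ends,
        valid=valid,
        costs=np.full(shape, np.inf),
        scores=np.full(shape, -np.inf),
        params=np.full(shape, None, dtype=object),
    )


def score_variants(
    grid: VariantGrid,
    signal: ContinuousSignal,
    centroid: np.ndarray,
    alpha: float,
    **align_kwargs,
) -> VariantGrid:
    """Align every valid variant to the centroid; record cost and params."""
    values = signal.values
    for i in range(grid.starts.shape[0]):
        for j in range(grid.starts.shape[1]):
            if not grid.valid[i, j]:
                continue
            seq = values[:, grid.starts[i, j] : grid.ends[i, j]]
            p = linear_align(seq, centroid, alpha=alpha, **align_kwargs)
            grid.costs[i, j] = p.cost
            grid.params[i, j] = p
    return grid


def costs_to_scores(costs: Sequence[float], cluster_ids: Sequence[int]) -> np.ndarray:
    """Per-cluster normalization of costs into scores = 1 - cost/max.

    Normalizing within each cluster avoids score skew between imbalanced
    clusters; an all-zero-cost cluster scores 1 everywhere.
    """
    costs = np.asarray(costs, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if np.any(costs < 0):
        raise ValueError("costs must be >= 0")
    scores = np.empty_like(costs)
    for c in np.unique(cluster_ids):
        sel = cluster_ids == c
        cmax = costs[sel].max()
        scores[sel] = 1.0 - (costs[sel] / cmax if cmax > 0 else 0.0)
    return scores


# ---------------------------------------------------------------------------
# overlap elimination (weighted interval scheduling)


def select_nonoverlapping(candidates: Sequence[tuple[tuple[int, int], float]]) -> list[int]:
    """Score-maximal subset of pairwise non-overlapping half-open intervals.

    Exact weighted-interval-scheduling dynamic program; candidates with
    non-finite scores are ignored.  Ties between equal-score optima break
    deterministically toward earlier starts, then shorter intervals, then
    lower input index.  Returns input indices sorted by interval start.
    """
    items = [
        (iv[0], iv[1], float(s), idx)
        for idx, (iv, s) in enumerate(candidates)
        if np.isfinite(s)
    ]
    if not items:
        return []
    # sort by end; tie-break keys keep the DP deterministic
    items.sort(key=lambda x: (x[1], x[0], x[1] - x[0], x[3]))
    ends = [it[1] for it in items]
    n = len(items)
    best = np.zeros(n + 1)
    take = np.zeros(n, dtype=bool)
    prev = np.zeros(n, dtype=int)
    for i, (s, e, sc, idx) in enumerate(items):
        p = bisect.bisect_right(ends, s, hi=i)  # intervals ending <= start
        prev[i] = p
        with_i = best[p] + sc
        without_i = best[i]
        # ties prefer taking, which favors earlier-start equal-score optima
        if with_i >= without_i:
            best[i + 1] = with_i
            take[i] = True
        else:
            best[i + 1] = without_i
    chosen: list[int] = []
    i = n - 1
    while i >= 0:
        if take[i] and best[i + 1] == best[prev[i]] + items[i][2]:
            chosen.append(items[i][3])
            i = prev[i] - 1
        else:
            i -= 1
    chosen.sort(key=lambda idx: candidates[idx][0][0])
    return chosen


# ---------------------------------------------------------------------------
# gap reassignment


def _active_cumsum(active: Optional[np.ndarray]) -> Optional[np.ndarray]:
    if active is None:
        return None
    return np.concatenate([[0], np.cumsum(active.astype(int))])


def _active_enough(acum: Optional[np.ndarray], start: int, end: int) -> bool:
    """The validity rule: >= 90% of the interval inside activity periods."""
    if acum is None:
        return True
    return (acum[end] - acum[start]) >= 0.9 * (end - start)


def _gaps(selected: list[Segment], T: int) -> list[tuple[int, int]]:
    """Unassigned stretches, including the recording's flanks."""
    tree = IntervalTree()
    for s in selected:
        tree.addi(s.start, s.end)
    tree.merge_overlaps()
    gaps = []
    cursor = 0
    for iv in sorted(tree):
        if iv.begin > cursor:
            gaps.append((cursor, iv.begin))
        cursor = iv.end
    if cursor < T:
        gaps.append((cursor, T))
    return gaps


def reassign_gaps(
    selected: list[Segment],
    signal: ContinuousSignal,
    clusters: list[ClusterState],
    mean_segment_length: int,
    stride: int,
    active: Optional[np.ndarray] = None,
) -> list[Segment]:
    """Reinstate motif-like windows inside significantly large gaps.

    A gap qualifies when its duration is at least the mean segment length.
    Windows of that length slide at ``stride``; a window is a candidate
    when its weighted Euclidean distance to the nearest centroid is below
    that cluster's mean within-cluster distance (from the outlier-removal
    statistics).  Candidate distances are converted to scores per cluster
    and resolved by non-overlapping selection inside each gap.

    The strict 90% activity rule is not applied here — windows have a fixed
    length, so a short motif inside a longer window would otherwise be
    unrecoverable — but at least two-thirds of a candidate window must be
    active, which rejects windows holding only filter smear and rest while
    still admitting a short motif inside a mean-length window.
    """
    if not clusters or mean_segment_length < 2:
        return list(selected)
    w = int(mean_segment_length)
    stride = max(1, int(stride))
    acum = _active_cumsum(active)
    out = list(selected)
    for g0, g1 in _gaps(selected, signal.n_frames):
        if g1 - g0 < w:
            continue
        cand: list[tuple[tuple[int, int], float, int]] = []  # interval, dist, cluster
        for start in range(g0, g1 - w + 1, stride):
            if acum is not None and (acum[start + w] - acum[start]) < (2.0 / 3.0) * w:
                continue
            window = signal.values[:, start : start + w]
            dists = [weighted_euclidean(window, c.centroid) for c in clusters]
            k = int(np.argmin(dists))
            if dists[k] < clusters[k].mean_pairwise_distance:
                cand.append(((start, start + w), float(dists[k]), clusters[k].cluster_id))
        if not cand:
            continue
        scores = costs_to_scores([c[1] for c in cand], [c[2] for c in cand])
        picked = select_nonoverlapping([(c[0], sc) for c, sc in zip(cand, scores)])
        for idx in picked:
            (s0, s1), _, cid = cand[idx]
            out.append(Segment(s0, s1, label=cid, score=float(scores[idx])))
    out.sort(key=lambda s: s.start)
    assert_nonoverlapping(out)
    return out


# ---------------------------------------------------------------------------
# the epoch loop


@dataclass
class TASCState:
    """Segments plus everything derived from them within an epoch."""

    segments: list[Segment]
    embeddings: np.ndarray
    memberships: np.ndarray
    clusters: list[ClusterState] = field(default_factory=list)
    embedder: Optional[PCAEmbedder] = None

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)


def _epoch_metrics(
    state: TASCState,
    epoch: int,
    truth: Optional[evaluation.GroundTruth],
    match_rule: str,
) -> dict:
    row: dict = {"epoch": epoch, "n_segments": len(state.segments)}
    costs = [s.align.cost for s in state.segments if s.align is not None]
    row["mean_cost"] = float(np.mean(costs)) if costs else np.nan
    labels = state.labels
    try:
        sil, ch = evaluation.clustering_indices(state.embeddings, labels)
    except ValueError:
        sil, ch = np.nan, np.nan
    row["silhouette"], row["calinski_harabasz"] = sil, ch
    if truth is not None:
        matches = evaluation.match_segments(state.segments, truth, rule=match_rule)
        row["iou_vs_truth"] = evaluation.mean_iou(state.segments, truth, rule=match_rule)
        row["boundary_l1_vs_truth"] = evaluation.boundary_l1(matches, state.segments, truth)
        _, recall = evaluation.confusion_and_recall(matches, labels, truth)
        row["recall_vs_truth"] = recall
    return row


def run_epoch(
    state: TASCState,
    signal: ContinuousSignal,
    config: TASCConfig,
    epoch: int,
    active: Optional[np.ndarray] = None,
    embedder: Optional[PCAEmbedder] = None,
) -> TASCState:
    """One full refinement pass; returns the new state.

    ``active`` is the per-frame activity mask; candidate variants and gap
    windows must keep >= 90% of their duration inside activity periods,
    preventing rest stretches from being claimed as motifs.
    """
    values = signal.values
    T = signal.n_frames
    L_range = config.L_at(epoch)
    alpha = config.alpha_at(epoch)
    align_kwargs = config._align_kwargs()
    acum = _active_cumsum(active)

    # 1-2: outlier removal and centroids per cluster
    by_cluster: dict[int, list[int]] = {}
    for idx, seg in enumerate(state.segments):
        by_cluster.setdefault(int(seg.label), []).append(idx)

    clusters: list[ClusterState] = []
    survivors: list[int] = []
    for cid, member_idx in sorted(by_cluster.items()):
        seqs = [values[:, state.segments[i].start : state.segments[i].end] for i in member_idx]
        kept, removed, mean_d, std_d = remove_outliers(seqs, config.gamma, config.outlier_center)
        if not kept:
            logger.warning("cluster %d emptied by outlier removal; dropping", cid)
            continue
        centroid = compute_centroid(
            [seqs[i] for i in kept], config.centroid_method, config.centroid_existing
        )
        clusters.append(
            ClusterState(
                cluster_id=cid,
                member_ids=[member_idx[i] for i in kept],
                centroid=centroid,
                mean_pairwise_distance=mean_d,
                distance_std=std_d,
                removed_ids=[member_idx[i] for i in removed],
            )
        )
        survivors.extend(member_idx[i] for i in kept)

    centroid_of = {c.cluster_id: c.centroid for c in clusters}

    # 3: variant generation and alignment scoring
    cand_intervals: list[tuple[int, int]] = []
    cand_costs: list[float] = []
    cand_cluster: list[int] = []
    cand_params: list[AlignmentParams] = []
    for sid in sorted(survivors):
        seg = state.segments[sid]
        cid = int(seg.label)
        grid = generate_variants(
            seg, config.M, L_range, T, segment_id=sid,
            m_step=config.m_step, l_step=config.l_step,
        )
        if acum is not None:
            for i in range(grid.starts.shape[0]):
                for j in range(grid.starts.shape[1]):
                    if grid.valid[i, j] and not _active_enough(
                        acum, int(grid.starts[i, j]), int(grid.ends[i, j])
                    ):
                        grid.valid[i, j] = False
        grid = score_variants(grid, signal, centroid_of[cid], alpha, **align_kwargs)
        for i in range(grid.starts.shape[0]):
            for j in range(grid.starts.shape[1]):
                if grid.valid[i, j] and grid.params[i, j] is not None:
                    cand_intervals.append((int(grid.starts[i, j]), int(grid.ends[i, j])))
                    cand_costs.append(float(grid.costs[i, j]))
                    cand_cluster.append(cid)
                    cand_params.append(grid.params[i, j])

    if not cand_intervals:
        logger.warning("no valid variants at epoch %d; state unchanged", epoch)
        return state

    # 4: per-cluster cost -> score conversion, then global overlap elimination
    cand_scores = costs_to_scores(cand_costs, cand_cluster)
    picked = select_nonoverlapping(list(zip(cand_intervals, cand_scores)))
    selected = [
        Segment(
            cand_intervals[i][0],
            cand_intervals[i][1],
            label=cand_cluster[i],
            score=float(cand_scores[i]),
            align=cand_params[i],
        )
        for i in picked
    ]
    selected.sort(key=lambda s: s.start)

    # 5: warp-align selected segments, resample to mean length, re-embed, re-cluster
    mean_len = max(2, int(round(np.mean([s.length for s in selected]))))
    if not config.refit_embedder and embedder is not None:
        # reuse the previously fitted embedder: its flattened input width
        # fixes the resample length
        target_len = embedder.target_length
    else:
        target_len = mean_len
    aligned = [
        warp_sequence(values[:, s.start : s.end], s.align, target_len, s.length)
        for s in selected
    ]
    X = np.stack([a.ravel() for a in aligned])
    if config.refit_embedder or embedder is None:
        n_comp = config.n_components
        if isinstance(n_comp, int):
            n_comp = min(n_comp, X.shape[0], X.shape[1])
        embedder = PCAEmbedder(n_components=n_comp, target_length=target_len)
        emb = embedder.fit_transform(X)
    else:
        emb = embedder.transform(X)

    k = min(len(clusters), len(selected))
    old_labels = np.array([s.label for s in selected])
    if k >= 2:
        fcm = FuzzyCMeans(k, fuzziness=config.fuzziness, seed=config.seed + epoch)
        new_labels, memberships = fcm.fit_assign(emb)
        # translate the epoch's cluster ids into the new labeling by majority
        # vote, so gap windows matched to an old centroid get a live label
        old_to_new: dict[int, int] = {}
        for c in clusters:
            votes = new_labels[np.isin(np.arange(len(selected)), np.flatnonzero(old_labels == c.cluster_id))]
            if len(votes):
                old_to_new[c.cluster_id] = int(np.bincount(votes).argmax())
        for seg, lab in zip(selected, new_labels):
            seg.label = int(lab)
    else:
        memberships = np.ones((len(selected), 1))
        old_to_new = {c.cluster_id: c.cluster_id for c in clusters}

    # 6: gap reassignment against the epoch's centroids and statistics
    n_before = len(selected)
    with_gaps = reassign_gaps(
        selected, signal, clusters, mean_len,
        max(1, int(round(config.gap_stride_fraction * mean_len))),
        active=active,
    )
    # reassign_gaps sorts; recover the appended windows by identity
    known = {id(s) for s in selected}
    appended = [s for s in with_gaps if id(s) not in known]
    extra_rows = []
    extra_members = []
    for seg in appended:
        mapped = old_to_new.get(int(seg.label))
        if mapped is None:
            continue
        seg.label = mapped
        vec = embedder.transform(
            resample_sequence(values[:, seg.start : seg.end], target_len).ravel()[None, :]
        )
        extra_rows.append(vec[0])
        onehot = np.zeros(memberships.shape[1])
        onehot[mapped if mapped < memberships.shape[1] else 0] = 1.0
        extra_members.append(onehot)
        selected.append(seg)
    if extra_rows:
        emb = np.vstack([emb, np.stack(extra_rows)])
        memberships = np.vstack([memberships, np.stack(extra_members)])

    order = np.argsort([s.start for s in selected], kind="stable")
    selected = [selected[i] for i in order]
    emb = emb[order]
    memberships = memberships[order]
    assert_nonoverlapping(selected)

    return TASCState(selected, emb, memberships, clusters, embedder)


@dataclass
class TASCResult:
    state: TASCState
    metrics: list[dict]
    initial_state: TASCState
    converged_at: Optional[int] = None


def _initialize(
    signal: ContinuousSignal,
    config: TASCConfig,
    init: Optional[list[Segment]],
    mask=None,
) -> TASCState:
    T = signal.n_frames
    if init is not None:
        for s in init:
            if s.start < 0 or s.end > T:
                raise ValueError(
                    f"external segment [{s.start},{s.end}) outside signal [0,{T})"
                )
        segments = sorted(init, key=lambda s: s.start)
        target = max(2, int(round(np.mean([s.length for s in segments]))))
        embedder = PCAEmbedder(
            n_components=min(config.n_components, len(segments))
            if isinstance(config.n_components, int) else config.n_components,
            target_length=target,
        )
        emb = embed_segments(signal, segments, embedder)
        labels = np.array([s.label for s in segments])
        k = len(np.unique(labels[labels >= 0]))
        memberships = np.zeros((len(segments), max(k, 1)))
        uniq = {c: i for i, c in enumerate(sorted(np.unique(labels[labels >= 0])))}
        for i, l in enumerate(labels):
            if l >= 0:
                memberships[i, uniq[int(l)]] = 1.0
        return TASCState(segments, emb, memberships, embedder=embedder)

    segments = naive_segmentation(signal, config.window, config.stride)
    if mask is not None:
        if config.trim_initial:
            # compensate the low-pass filter's edge attenuation when cropping
            edge_pad = int(round(signal.frame_rate / (2 * np.pi * config.activity_cutoff_hz)))
            trimmed = trim_segments_to_activity(
                segments, mask, min_length=max(2, config.window // 2),
                edge_pad=edge_pad,
            )
            if trimmed:
                segments = trimmed
            else:
                logger.warning("activity trimming removed every window; keeping all")
        else:
            valid = filter_valid_segments(segments, mask)
            if valid:
                segments = valid
            else:
                logger.warning("activity filter removed every window; keeping all")
    if len(segments) < 2:
        raise ValueError("initialization produced fewer than 2 segments")

    n_comp = config.n_components
    if isinstance(n_comp, int):
        n_comp = min(n_comp, len(segments))
    embedder = PCAEmbedder(n_components=n_comp, target_length=config.window)
    emb = embed_segments(signal, segments, embedder)

    if config.dilution:
        segments, emb = spatiotemporal_dilution(
            segments, emb, config.dilution_max_overlap, config.dilution_latent_radius
        )

    if config.n_clusters is not None:
        k = config.n_clusters
    else:
        from .embedding import select_cluster_count

        lo, hi = config.k_range or (2, min(10, len(segments) - 1))
        k = select_cluster_count(
            emb, range(lo, hi + 1), fuzziness=config.fuzziness, seed=config.seed
        )
    k = min(k, len(segments))
    fcm = FuzzyCMeans(k, fuzziness=config.fuzziness, seed=config.seed)
    labels, memberships = cluster_segments(emb, fcm)
    # membership of the assigned cluster doubles as the selection score
    for i, seg in enumerate(segments):
        seg.label = int(labels[i])
        seg.score = float(memberships[i, labels[i]])

    # overlapping naive candidates (stride < window): resolve by DP on scores
    stride = config.stride if config.stride is not None else config.window
    if stride < config.window:
        picked = select_nonoverlapping(
            [((s.start, s.end), s.score or 0.0) for s in segments]
        )
        segments = [segments[i] for i in picked]
        emb = emb[picked]
        memberships = memberships[picked]

    return TASCState(list(segments), emb, memberships, embedder=embedder)


def _boundary_change_fraction(prev: list[Segment], cur: list[Segment]) -> float:
    if len(prev) != len(cur):
        return 1.0
    moved = sum(
        1
        for a, b in zip(prev, cur)
        if abs(a.start - b.start) > 1 or abs(a.end - b.end) > 1
    )
    return moved / max(len(cur), 1)


def run_tasc(
    signal: ContinuousSignal,
    config: TASCConfig,
    init: Optional[list[Segment]] = None,
    truth: Optional[evaluation.GroundTruth] = None,
) -> TASCResult:
    """End-to-end refinement: preprocess, initialize, iterate epochs.

    ``init`` bypasses the internal naive segmentation (e.g. boundaries
    imported from another framework).  When ``truth`` is supplied the
    per-epoch metric trace includes IoU, summed boundary L1 and recall
    against it.  Fully reproducible for a fixed config seed.
    """
    if config.normalize:
        signal = normalize_signal(signal)
    mask = None
    if config.use_activity_filter:
        mask = detect_activity_periods(
            signal,
            config.activity_cutoff_hz,
            config.activity_quantile,
            config.activity_min_frames,
        )
    state = _initialize(signal, config, init, mask)
    metrics = [_epoch_metrics(state, 0, truth, config.match_rule)]
    logger.info("init: %s", metrics[-1])
    initial_state = state
    converged_at = None
    active = mask.active if mask is not None else None
    for epoch in range(1, config.epochs + 1):
        prev_segments = state.segments
        state = run_epoch(state, signal, config, epoch, active=active,
                          embedder=state.embedder)
        metrics.append(_epoch_metrics(state, epoch, truth, config.match_rule))
        logger.info("epoch %d: %s", epoch, metrics[-1])
        frac = _boundary_change_fraction(prev_segments, state.segments)
        if frac < config.convergence_fraction:
            converged_at = epoch
            logger.info("converged at epoch %d (%.3f%% boundaries moved)", epoch, 100 * frac)
            break
    return TASCResult(state, metrics, initial_state, converged_at)
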