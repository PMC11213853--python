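"""Segmentation and clustering metrics against a ground truth.

Segmentation quality is measured by interval IoU and the summed L1 distance
between corresponding boundaries; correspondence is a greedy one-to-one
matching in decreasing-IoU order, admitting a (prediction, truth) pair when
their intersection covers at least half of the truth segment's duration
(an ``iou >= 0.5`` admissibility rule is available instead).  Cluster
labels are permutation-aligned to truth classes by a Hungarian assignment
on the match-count matrix before recall and the confusion matrix are read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .segments import Segment, assert_nonoverlapping

__all__ = [
    "GroundTruth",
    "interval_iou",
    "match_segments",
    "mean_iou",
    "boundary_l1",
    "confusion_and_recall",
    "clustering_indices",
]


@dataclass
class GroundTruth:
    segments: list[Segment]
    n_classes: int

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start)
        assert_nonoverlapping(self.segments)


def interval_iou(a: Segment, b: Segment) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = a.length + b.length - inter
    return inter / union if union else 0.0


def match_segments(
    pred: list[Segment],
    truth: GroundTruth,
    rule: str = "half_duration",
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching, returns (pred_idx, truth_idx, iou) triples.

    ``rule="half_duration"``: a pair is admissible iff the intersection is
    at least half the truth segment's duration; ``rule="iou"``: iff
    IoU >= 0.5.  Ties in IoU break toward the earlier truth start, then
    earlier prediction.
    """
    pairs = []
    for pi, p in enumerate(pred):
        for ti, t in enumerate(truth.segments):
            inter = min(p.end, t.end) - max(p.start, t.start)
            if inter <= 0:
                continue
            iou = interval_iou(p, t)
            if rule == "half_duration":
                ok = inter >= 0.5 * t.length
            elif rule == "iou":
                ok = iou >= 0.5
            else:
                raise ValueError(f"unknown correspondence rule {rule!r}")
            if ok:
                pairs.append((iou, t.start, pi, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for iou, _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti, iou))
    return matches


def mean_iou(
    pred: list[Segment],
    truth: GroundTruth,
    count_unmatched: bool = True,
    rule: str = "half_duration",
) -> float:
    """Average IoU over truth segments; unmatched truths count as 0 by default."""
    matches = match_segments(pred, truth, rule=rule)
    total = sum(m[2] for m in matches)
    denom = len(truth.segments) if count_unmatched else max(len(matches), 1)
    return total / denom if denom else 0.0


def boundary_l1(
    matches: list[tuple[int, int, float]],
    pred: list[Segment],
    truth: GroundTruth,
) -> float:
    """Summed |start - start| + |end - end| over matched pairs (frames)."""
    return float(
        sum(
            abs(pred[pi].start - truth.segments[ti].start)
            + abs(pred[pi].end - truth.segments[ti].end)
            for pi, ti, _ in matches
        )
    )


def confusion_and_recall(
    matches: list[tuple[int, int, float]],
    pred_labels: np.ndarray,
    truth: GroundTruth,
) -> tuple[np.ndarray, float]:
    """(K+1) x (C+1) confusion matrix normalized by truth count, plus recall.

    Cluster ids carry no semantics across epochs, so clusters are mapped to
    truth classes by maximal agreement (Hungarian assignment on match
    counts).  The extra row/column holds unmatched predictions/truths.
    Recall = matched truths whose mapped cluster equals their class, over
    all truths.
    """
    pred_labels = np.asarray(pred_labels)
    clusters = sorted(set(int(l) for l in pred_labels))
    cindex = {c: i for i, c in enumerate(clusters)}
    K, C = len(clusters), truth.n_classes
    counts = np.zeros((max(K, 1), C))
    for pi, ti, _ in matches:
        counts[cindex[int(pred_labels[pi])], truth.segments[ti].label] += 1
    if K:
        rows, cols = linear_sum_assignment(-counts)
        mapping = {clusters[r]: int(c) for r, c in zip(rows, cols)}
    else:
        mapping = {}

    # order cluster rows by their mapped class so a perfect prediction
    # yields an identity block
    row_order = sorted(clusters, key=lambda c: (mapping.get(c, C), c))
    row_of = {c: i for i, c in enumerate(row_order)}

    conf = np.zeros((K + 1, C + 1))
    matched_t = set()
    matched_p = set()
    correct = 0
    for pi, ti, _ in matches:
        cid = int(pred_labels[pi])
        tclass = truth.segments[ti].label
        conf[row_of[cid], tclass] += 1
        matched_t.add(ti)
        matched_p.add(pi)
        if mapping.get(cid) == tclass:
            correct += 1
    for ti, t in enumerate(truth.segments):
        if ti not in matched_t:
            conf[K, t.label] += 1
    for pi in range(len(pred_labels)):
        if pi not in matched_p:
            conf[row_of[int(pred_labels[pi])], C] += 1
    n_true = len(truth.segments)
    conf /= max(n_true, 1)
    recall = correct / n_true if n_true else 0.0
    return conf, recall


def clustering_indices(embeddings: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Silhouette and Calinski-Harabasz internal indices."""
    X = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("clustering indices require >= 2 clusters")
    return (
        float(silhouette_score(X, labels)),
        float(calinski_harabasz_score(X, labels)),
    )
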