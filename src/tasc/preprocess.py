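"""Signal normalization, activity-period detection and segment validation.

A recording enters the pipeline as a :class:`ContinuousSignal` — a dense
``D features x T frames`` matrix (e.g. pairwise landmark distances, joint
positions or velocities).  Before segmentation the signal is min-max
normalized per feature, and stretches of inactivity are masked out so that
rest periods do not dominate the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ContinuousSignal",
    "ActivityMask",
    "normalize_signal",
    "detect_activity_periods",
    "filter_valid_segments",
]


@dataclass
class ContinuousSignal:
    """A multichannel recording: ``values`` is D features x T frames."""

    values: np.ndarray
    frame_rate: float = 30.0
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("signal values must be a 2-D (features x frames) array")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[0])]
        if len(self.feature_names) != self.values.shape[0]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ActivityMask:
    """Boolean per-frame activity flags plus the energy trace behind them."""

    active: np.ndarray
    threshold_used: float
    smoothed_energy: np.ndarray


def _check_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        d, t = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"signal contains a non-finite value at feature {d}, frame {t}"
        )


def normalize_signal(signal: ContinuousSignal) -> ContinuousSignal:
    """Min-max scale every feature to [0, 1]; constant features map to 0.

    Idempotent: a signal already in [0, 1] per feature whose extremes are
    attained is returned unchanged (up to floating point).
    """
    _check_finite(signal.values)
    lo = signal.values.min(axis=1, keepdims=True)
    hi = signal.values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (signal.values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ContinuousSignal(out, signal.frame_rate, list(signal.feature_names))


def detect_activity_periods(
    signal: ContinuousSignal,
    cutoff_hz: float = 1.0,
    threshold_quantile: float = 0.25,
    min_period_frames: int = 5,
) -> ActivityMask:
    """Flag frames with enough movement energy to host behavior motifs.

    Energy is the per-frame sum over features of the absolute first
    difference; it is smoothed with a zero-phase Butterworth low-pass
    (``cutoff_hz``) and thresholded at ``threshold_quantile`` of its
    distribution.  Active runs shorter than ``min_period_frames`` are
    dropped.
    """
    T = signal.n_frames
    if T < 3:
        raise ValueError("signal too short for activity detection (T < 3)")
    if not 0 < cutoff_hz < signal.frame_rate / 2:
        raise ValueError("cutoff_hz must lie in (0, frame_rate/2)")
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must lie in (0, 1)")

    diffs = np.abs(np.diff(signal.values, axis=1)).sum(axis=0)
    energy = np.concatenate([[diffs[0]], diffs])  # length T, frame 0 copies frame 1

    if np.allclose(energy, 0):
        smoothed = energy
        threshold = 0.0
        active = np.zeros(T, dtype=bool)
        return ActivityMask(active, threshold, smoothed)

    b, a = sps.butter(2, cutoff_hz / (signal.frame_rate / 2))
    padlen = min(3 * max(len(a), len(b)), T - 1)
    smoothed = sps.filtfilt(b, a, energy, padlen=padlen)
    threshold = float(np.quantile(smoothed, threshold_quantile))
    active = smoothed >= threshold

    # suppress runs shorter than min_period_frames
    if min_period_frames > 1:
        padded = np.concatenate([[False], active, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start < min_period_frames:
                active[start:end] = False

    return ActivityMask(active, threshold, smoothed)


def filter_valid_segments(segments, mask: ActivityMask):
    """Keep segments with >= 90% of their frames inside activity periods."""
    kept = []
    active = mask.active
    for seg in segments:
        length = seg.end - seg.start
        if length <= 0:
            continue
        frac = active[seg.start : seg.end].sum() / length
        if frac >= 0.9:
            kept.append(seg)
    return kept


def trim_segments_to_activity(segments, mask: ActivityMask, min_length: int = 2,
                              edge_pad: int = 0):
    """Trim each segment to the activity run it overlaps most; drop the rest.

    Rest frames at a window's tails otherwise contaminate embeddings and
    freeze into cluster centroids.  Each segment shrinks to its
    intersection with the single active run covering most of it; segments
    left shorter than ``min_length`` (or touching no run) are dropped, and
    exact duplicates arising from overlapping windows trimmed to the same
    core are collapsed.

    ``edge_pad`` re-extends each trimmed boundary outward by a fixed number
    of frames (clipped to the signal), compensating the movement-energy
    attenuation at motif edges introduced by the low-pass smoothing: a
    second-order filter at cutoff f_c loses roughly fs/(2*pi*f_c) frames of
    genuine motion on each side of an activity run.
    """
    T = len(mask.active)
    padded = np.concatenate([[False], mask.active, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = list(zip(edges[::2], edges[1::2]))  # half-open [start, end)
    out = []
    seen: set[tuple[int, int]] = set()
    for seg in segments:
        best = None
        best_ov = 0
        for r0, r1 in runs:
            ov = min(seg.end, r1) - max(seg.start, r0)
            if ov > best_ov:
                best_ov = ov
                best = (max(seg.start, r0), min(seg.end, r1))
        if best is None or best[1] - best[0] < max(min_length, 2):
            continue
        interval = (max(0, best[0] - edge_pad), min(T, best[1] + edge_pad))
        if interval in seen:
            continue
        seen.add(interval)
        out.append(type(seg)(interval[0], interval[1], seg.label, seg.score, seg.align))
    return out
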