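"""Ground-truthed semi-synthetic recordings for validating refinement.

The protocol mirrors how behavior recordings are emulated for evaluation: a
small library of multichannel motifs (defaults: five motifs of 60-90 frames,
as one would hand-pick single cycles of distinguishable behaviors), each
replicated under uniformly random linear warps (offset tau ~ U(-0.1, 0.1),
slope s ~ U(0.8, 1.2)), inserted in random order on a constant baseline
equal to the mean value across motifs, min-max normalized to [0, 1], and
overlaid with Gaussian white noise (sigma = 0.01).  True boundaries, labels
and warp draws are retained, so segmentation and clustering can be scored
against an exact ground truth.

The motifs here are fully synthetic (sums of low-frequency sinusoids and
Gaussian bumps); users may supply their own motif matrices, e.g. snippets
cut from real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import warp_sequence, weighted_euclidean
from .evaluation import GroundTruth
from .preprocess import ContinuousSignal
from .segments import AlignmentParams, Segment

__all__ = [
    "MotifLibrary",
    "SyntheticDataset",
    "make_motif_library",
    "warp_motif",
    "assemble_signal",
]

TAU_RANGE = (-0.1, 0.1)
S_RANGE = (0.8, 1.2)


@dataclass
class MotifLibrary:
    motifs: list[np.ndarray]
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(range(len(self.motifs)))

    @property
    def n_features(self) -> int:
        return self.motifs[0].shape[0]


@dataclass
class SyntheticDataset:
    signal: ContinuousSignal
    truth: GroundTruth
    warp_record: list[AlignmentParams]
    seed: int


def _smooth_motif(rng: np.random.Generator, length: int, n_features: int) -> np.ndarray:
    """One motif: per feature, 1-3 low-frequency sinusoid/bump components.

    A gentle envelope tapers each feature toward rest at the boundaries,
    mimicking the bell-shaped speed profile of natural sub-movements, which
    begin and end at low velocity.
    """
    t = np.linspace(0, 1, length)
    motif = np.zeros((n_features, length))
    for d in range(n_features):
        for _ in range(rng.integers(1, 4)):
            if rng.random() < 0.5:
                freq = rng.uniform(0.5, 2.5)
                phase = rng.uniform(0, 2 * np.pi)
                motif[d] += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * t + phase)
            else:
                center = rng.uniform(0.2, 0.8)
                width = rng.uniform(0.05, 0.25)
                motif[d] += rng.uniform(0.3, 1.0) * np.exp(-((t - center) ** 2) / (2 * width**2))
        motif[d] *= np.hanning(length) ** 0.5
    return motif


def make_motif_library(
    n_motifs: int = 5,
    length_range: tuple[int, int] = (60, 90),
    n_features: int = 5,
    seed: int = 0,
    min_distance: float = 1.0,
    motifs: list[np.ndarray] | None = None,
) -> MotifLibrary:
    """Draw smooth, mutually distinguishable multichannel motifs.

    Deterministic per seed.  Candidate sets whose minimum pairwise weighted
    Euclidean distance falls below ``min_distance`` are redrawn (bounded
    retries), so the library never contains near-duplicates.  A
    user-supplied ``motifs`` list is wrapped verbatim.
    """
    if motifs is not None:
        return MotifLibrary([np.atleast_2d(np.asarray(m, dtype=float)) for m in motifs])
    if n_motifs < 2:
        raise ValueError("need at least 2 motifs")
    if length_range[0] < 4:
        raise ValueError("motif length_range must start at >= 4 frames")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_motifs)
        cand = [_smooth_motif(rng, int(L), n_features) for L in lengths]
        dmin = min(
            weighted_euclidean(cand[i], cand[j])
            for i in range(n_motifs)
            for j in range(i + 1, n_motifs)
        )
        if dmin >= min_distance:
            return MotifLibrary(cand)
    raise RuntimeError("could not draw sufficiently distinct motifs; lower min_distance")


def warp_motif(motif: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, AlignmentParams]:
    """One warped instance of a motif, with its recorded warp draw.

    The variant samples ``motif(tau + t*s)`` at ``round(len/s)`` points, so
    slower executions (s < 1) come out longer.  With the draw recorded and
    the original length known, the variant is exactly reconstructible.
    """
    motif = np.atleast_2d(np.asarray(motif, dtype=float))
    L = motif.shape[1]
    tau = float(rng.uniform(*TAU_RANGE))
    s = float(rng.uniform(*S_RANGE))
    out_length = max(2, int(round(L / s)))
    params = AlignmentParams(tau, s)
    return warp_sequence(motif, params, out_length, domain_length=L), params


def assemble_signal(
    library: MotifLibrary,
    n_variants_per_motif: int = 20,
    noise_sigma: float = 0.01,
    seed: int = 0,
    gap_range: tuple[int, int] = (30, 90),
    frame_rate: float = 120.0,
    identity_warps: bool = False,
) -> SyntheticDataset:
    """Concatenate warped motif variants into a continuous ground-truthed signal.

    Variants of all motifs are shuffled into a seeded random order and laid
    on a constant per-feature baseline (the mean over all motifs and
    frames), separated by baseline gaps of uniformly drawn length (set
    ``gap_range=(0, 0)`` for back-to-back insertion).  The assembled signal
    is min-max normalized to [0, 1] and independent N(0, noise_sigma^2)
    noise is added to every sample.
    """
    if n_variants_per_motif < 1:
        raise ValueError("n_variants_per_motif must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    D = library.n_features
    baseline = np.mean([m.mean(axis=1) for m in library.motifs], axis=0)  # per feature

    order = np.repeat(np.arange(len(library.motifs)), n_variants_per_motif)
    rng.shuffle(order)

    def gap_len() -> int:
        if gap_range[1] <= 0:
            return 0
        return int(rng.integers(gap_range[0], gap_range[1] + 1))

    chunks: list[np.ndarray] = []
    truth_segments: list[Segment] = []
    warp_record: list[AlignmentParams] = []
    cursor = 0

    def push_gap() -> None:
        nonlocal cursor
        g = gap_len()
        if g > 0:
            chunks.append(np.broadcast_to(baseline[:, None], (D, g)).copy())
            cursor += g

    push_gap()
    for motif_id in order:
        if identity_warps:
            variant = library.motifs[motif_id].copy()
            params = AlignmentParams(0.0, 1.0)
        else:
            variant, params = warp_motif(library.motifs[motif_id], rng)
        chunks.append(variant)
        truth_segments.append(Segment(cursor, cursor + variant.shape[1], label=int(motif_id)))
        warp_record.append(params)
        cursor += variant.shape[1]
        push_gap()

    values = np.hstack(chunks)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    values = (values - lo) / span
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)

    signal = ContinuousSignal(values, frame_rate=frame_rate)
    truth = GroundTruth(truth_segments, n_classes=len(library.motifs))
    return SyntheticDataset(signal, truth, warp_record, seed)
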