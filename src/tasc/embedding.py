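"""Embedding (F_E) and cluster-assignment (F_C) with the default choices.

The framework is agnostic to how segments are embedded and clustered: any
object with the :class:`Embedder` fit/transform contract or the
:class:`Clusterer` fit/assign-with-scores contract can be plugged in (a
pretrained autoencoder, a density-based clusterer, ...).  The defaults here
are principal component analysis and fuzzy c-means, whose soft memberships
double as selection scores for overlap elimination.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .preprocess import ContinuousSignal
from .segments import Segment

__all__ = [
    "Embedder",
    "PCAEmbedder",
    "Clusterer",
    "FuzzyCMeans",
    "naive_segmentation",
    "resample_segment",
    "embed_segments",
    "cluster_segments",
    "select_cluster_count",
    "spatiotemporal_dilution",
]


def naive_segmentation(signal: ContinuousSignal, window: int, stride: int | None = None) -> list[Segment]:
    """Cut the recording into fixed-size windows [k*stride, k*stride+window).

    ``stride < window`` produces overlapping candidates; overlaps are
    resolved downstream by score-maximal non-overlapping selection.
    """
    T = signal.n_frames
    if window > T:
        raise ValueError(f"window {window} exceeds signal length {T}")
    if window < 2:
        raise ValueError("window must be >= 2 frames")
    stride = window if stride is None else stride
    if not 1 <= stride <= window:
        raise ValueError("stride must lie in [1, window]")
    return [Segment(s, s + window) for s in range(0, T - window + 1, stride)]


def resample_segment(signal: ContinuousSignal, segment: Segment, target_length: int) -> np.ndarray:
    """Linearly interpolate a segment's slice onto ``target_length`` frames."""
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    sl = signal.values[:, segment.start : segment.end]
    return resample_sequence(sl, target_length)


def resample_sequence(seq: np.ndarray, target_length: int) -> np.ndarray:
    """Per-feature linear interpolation onto evenly spaced points.

    Endpoints are preserved: the first and last output frames equal the
    first and last input frames.
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    L = seq.shape[1]
    if L == target_length:
        return seq.copy()
    src = np.arange(L)
    dst = np.linspace(0, L - 1, target_length)
    return np.vstack([np.interp(dst, src, row) for row in seq])


class Embedder:
    """fit/transform contract for F_E."""

    target_length: int

    def fit(self, X: np.ndarray) -> "Embedder":
        raise NotImplementedError

    def transform(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


class PCAEmbedder(Embedder):
    """Default F_E: PCA on row-flattened (feature-major) resampled segments."""

    def __init__(self, n_components: int | float = 10, target_length: int = 90):
        self.n_components = n_components
        self.target_length = target_length
        self._pca: PCA | None = None

    def fit(self, X: np.ndarray) -> "PCAEmbedder":
        n_comp = self.n_components
        if isinstance(n_comp, int):
            cap = min(X.shape[0], X.shape[1])
            if n_comp > cap:
                raise ValueError(
                    f"{n_comp} components requested but only {cap} attainable "
                    f"from {X.shape[0]} segments; reduce n_components"
                )
        self._pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("embedder not fitted")
        return self._pca.transform(X)


def embed_segments(
    signal: ContinuousSignal,
    segments: list[Segment],
    embedder: Embedder,
    refit: bool = True,
) -> np.ndarray:
    """One latent vector per segment, in input order.

    Segments are resampled to the embedder's uniform ``target_length`` and
    row-flattened feature-major (feature 0 frames, then feature 1, ...).
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to embed")
    X = np.stack(
        [resample_segment(signal, s, embedder.target_length).ravel() for s in segments]
    )
    return embedder.fit_transform(X) if refit else embedder.transform(X)


class Clusterer:
    """fit/assign contract for F_C: returns hard labels and soft scores."""

    def fit_assign(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class FuzzyCMeans(Clusterer):
    """Bezdek fuzzy c-means.

    Memberships u_ik minimize sum_ik u_ik^m ||x_i - c_k||^2 subject to rows
    of u summing to 1; ``fuzziness`` m > 1 controls softness (m -> 1 gives
    hard k-means).  Centers are initialized from seeded random memberships,
    making the fit deterministic for a given seed.
    """

    def __init__(
        self,
        n_clusters: int,
        fuzziness: float = 2.0,
        seed: int = 0,
        max_iter: int = 1000,
        tol: float = 1e-6,
        n_init: int = 10,
    ):
        if n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if fuzziness <= 1:
            raise ValueError("fuzziness must be > 1")
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.centers_: np.ndarray | None = None

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        d2 = np.maximum(d2, 1e-12)
        expo = 1.0 / (self.fuzziness - 1.0)
        inv = d2 ** (-expo)
        return inv / inv.sum(axis=1, keepdims=True)

    def _objective(self, X: np.ndarray, u: np.ndarray, centers: np.ndarray) -> float:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        return float((u**self.fuzziness * d2).sum())

    def _run_once(self, X: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        u = rng.dirichlet(np.ones(self.n_clusters), size=X.shape[0])
        for _ in range(self.max_iter):
            um = u**self.fuzziness
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u_new = self._memberships(X, centers)
            if np.abs(u_new - u).max() < self.tol:
                u = u_new
                break
            u = u_new
        um = u**self.fuzziness
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        return u, centers

    def fit_assign(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.n_clusters:
            raise ValueError("fewer points than clusters")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate embeddings: all points identical")
        best_u, best_c, best_j = None, None, np.inf
        # restarts with derived seeds; keep the lowest FCM objective
        for r in range(self.n_init):
            u, centers = self._run_once(X, self.seed + 7919 * r)
            j = self._objective(X, u, centers)
            if j < best_j:
                best_u, best_c, best_j = u, centers, j
        self.centers_ = best_c
        labels = np.argmax(best_u, axis=1)
        return labels, best_u


def cluster_segments(embeddings: np.ndarray, clusterer: Clusterer) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (argmax membership) plus the soft membership matrix."""
    return clusterer.fit_assign(np.asarray(embeddings, dtype=float))


def select_cluster_count(
    embeddings: np.ndarray,
    k_range,
    clusterer_factory=None,
    fuzziness: float = 2.0,
    seed: int = 0,
) -> int:
    """Pick the cluster count maximizing mean silhouette; ties go small."""
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    X = np.asarray(embeddings, dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("silhouette undefined for identical points")
    if len(ks) == 1:
        return ks[0]
    best_k, best_score = None, -np.inf
    for k in sorted(ks):
        clusterer = (
            clusterer_factory(k) if clusterer_factory is not None
            else FuzzyCMeans(k, fuzziness=fuzziness, seed=seed)
        )
        labels, _ = clusterer.fit_assign(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no k in range produced >= 2 populated clusters")
    return best_k


def spatiotemporal_dilution(
    segments: list[Segment],
    embeddings: np.ndarray,
    max_overlap_fraction: float = 0.5,
    latent_radius: float | None = None,
) -> tuple[list[Segment], np.ndarray]:
    """Thin near-duplicate candidates that are close in both time and latent space.

    Greedy in input order: a segment is dropped when it overlaps an already
    retained segment by more than ``max_overlap_fraction`` of its own length
    AND its latent vector lies within ``latent_radius`` of that segment's.
    Default radius is the median nearest-neighbor latent distance.  Useful
    with dense striding at high acquisition rates, where consecutive windows
    are near copies.
    """
    E = np.asarray(embeddings, dtype=float)
    if len(segments) != len(E):
        raise ValueError("embeddings must align with segments")
    if not segments:
        return [], E
    if latent_radius is None:
        if len(segments) < 2:
            latent_radius = 0.0
        else:
            d = np.sqrt(((E[:, None, :] - E[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            latent_radius = float(np.median(d.min(axis=1)))
    kept_idx: list[int] = []
    for i, seg in enumerate(segments):
        drop = False
        for j in kept_idx:
            other = segments[j]
            ov = min(seg.end, other.end) - max(seg.start, other.start)
            if ov > max_overlap_fraction * seg.length and np.linalg.norm(E[i] - E[j]) <= latent_radius:
                drop = True
                break
        if not drop:
            kept_idx.append(i)
    return [segments[i] for i in kept_idx], E[kept_idx]
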