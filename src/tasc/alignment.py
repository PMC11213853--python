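"""Linear temporal alignment and the variable-length weighted distance.

Two sequences sharing an underlying shape may differ in phase and execution
speed.  A query ``x`` is mapped onto a template ``y`` by a single offset
``tau_w`` and a single slope ``s_w``::

    x_hat(t) = x(tau_w + t * s_w),   t in [0, 1)

with linear interpolation between frames; ``tau_w`` shifts the sequence in
time and ``s_w`` shrinks (s > 1) or stretches (s < 1) it.  Both parameters
act in the normalized t-domain of the query: a source position
``tau_w + t*s_w`` is scaled by the query's frame count before sampling.

The distance between the warped query and the template is a weighted
Euclidean distance: when lengths differ, the shorter sequence is padded at
its tail with its own per-feature median (+ a tiny epsilon breaking exact
ties) and every frame is weighted by ``1 + hamming(minlen)`` over the first
``minlen`` frames (baseline 1 elsewhere), emphasizing agreement in the
temporal center of a motif where its shape lives.  The full alignment loss
adds an arctangent penalty ``r = arctan|tau| + 1.5*arctan|s - 1|`` scaled by
``alpha``, discouraging extreme warps; the slope is penalized more heavily.

`linear_align` minimizes the loss over a bounded (tau, s) box with a
deterministic global search: dense vectorized sampling of the box followed
by iterative zoom refinement around the best basin.  ``method="shgo"`` runs
scipy's simplicial homology global optimizer instead; a dense grid search
is the fallback when the optimizer fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import shgo
from scipy.signal.windows import hamming

from .segments import AlignmentParams

__all__ = [
    "DistanceWeights",
    "build_weights",
    "weighted_euclidean",
    "warp_sequence",
    "warped_length",
    "penalty",
    "alignment_loss",
    "linear_align",
    "grid_align",
]

PAD_EPS = 1e-6
DEFAULT_TAU_BOUNDS = (-0.25, 0.25)
DEFAULT_S_BOUNDS = (0.5, 2.0)


@dataclass
class DistanceWeights:
    """Per-frame weights for the variable-length distance."""

    weights: np.ndarray
    minlen: int
    maxlen: int


def build_weights(len_x: int, len_y: int) -> DistanceWeights:
    """Raised-Hamming weights: 1 + hamming(minlen), then baseline 1."""
    if len_x < 2 or len_y < 2:
        raise ValueError("sequences must span at least 2 frames")
    minlen, maxlen = min(len_x, len_y), max(len_x, len_y)
    w = np.ones(maxlen)
    w[:minlen] += hamming(minlen, sym=True)
    return DistanceWeights(w, minlen, maxlen)


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def _padded_cost(a: np.ndarray, b: np.ndarray, pad_a: np.ndarray, pad_b: np.ndarray) -> float:
    """Weighted cost with explicit per-feature tail-padding values."""
    dw = build_weights(a.shape[1], b.shape[1])

    def pad(m: np.ndarray, fill: np.ndarray) -> np.ndarray:
        if m.shape[1] == dw.maxlen:
            return m
        tail = np.broadcast_to(
            fill[:, None] + PAD_EPS, (m.shape[0], dw.maxlen - m.shape[1])
        )
        return np.hstack([m, tail])

    diff = pad(a, pad_a) - pad(b, pad_b)
    return float(np.sqrt(np.einsum("dt,t->", diff * diff, dw.weights)))


def weighted_euclidean(x: np.ndarray, y: np.ndarray) -> float:
    """Distance between D x len_x and D x len_y sequences.

    The shorter sequence is tail-padded with its per-feature median + eps;
    the cost is sqrt(sum_d sum_t w[t] * (a - b)^2).  Zero iff the inputs
    are identical with equal length; symmetric for equal-length inputs.
    """
    a, b = _as_matrix(x), _as_matrix(y)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"feature-count mismatch: {a.shape[0]} vs {b.shape[0]}")
    return _padded_cost(a, b, np.median(a, axis=1), np.median(b, axis=1))


def warp_sequence(
    x: np.ndarray,
    params: AlignmentParams,
    out_length: int,
    domain_length: int | None = None,
) -> np.ndarray:
    """Sample ``x(tau_w + t*s_w)`` at ``out_length`` points of t in [0, 1).

    ``domain_length`` scales the normalized source positions onto x's frame
    axis (defaults to x's own length); out-of-range positions clamp to the
    edge frames so any parameter inside the search box is evaluable.
    """
    x = _as_matrix(x)
    if out_length < 2:
        raise ValueError("out_length must be >= 2")
    if domain_length is None:
        domain_length = x.shape[1]
    t = np.arange(out_length) / out_length
    pos = (params.tau_w + t * params.s_w) * domain_length
    pos = np.clip(pos, 0.0, x.shape[1] - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, x.shape[1] - 1)
    frac = pos - i0
    return x[:, i0] * (1.0 - frac) + x[:, i1] * frac


def penalty(params: AlignmentParams) -> float:
    """Warp regularizer; zero only at the identity (tau=0, s=1)."""
    return float(np.arctan(abs(params.tau_w)) + 1.5 * np.arctan(abs(params.s_w - 1.0)))


def warped_length(query_length: int, s_w: float) -> int:
    """A slope-s warp maps a length-L sequence onto round(L / s) frames.

    Slower renditions (s < 1) come out longer; the same rule governs both
    synthetic variant generation and the warped query inside the loss, so
    aligning a motif onto one of its warped variants recovers the
    generating parameters exactly.
    """
    return max(2, int(round(query_length / s_w)))


def alignment_loss(
    query: np.ndarray,
    template: np.ndarray,
    params: AlignmentParams,
    alpha: float = 0.0,
) -> float:
    """Weighted distance of the warped query to the template, plus alpha*r.

    The warped query is sampled at the template's length, so the residual
    distance measures shape mismatch after the warp has absorbed phase and
    speed differences; duration differences between query and template are
    bridged by the warp itself, not charged to the distance.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    q, tpl = _as_matrix(query), _as_matrix(template)
    warped = warp_sequence(q, params, tpl.shape[1], q.shape[1])
    return weighted_euclidean(warped, tpl) + alpha * penalty(params)


def _batch_loss(
    query: np.ndarray,
    template: np.ndarray,
    taus: np.ndarray,
    ss: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Vectorized alignment loss over P parameter pairs.

    Mirrors `alignment_loss`: the warped query is sampled at the template
    length, so every comparison is equal-length and the weights reduce to
    the raised Hamming window of that length.
    """
    q, tpl = _as_matrix(query), _as_matrix(template)
    Lq = q.shape[1]
    Lc = tpl.shape[1]
    taus = np.asarray(taus, dtype=float)
    ss = np.asarray(ss, dtype=float)

    k = np.arange(Lc)
    pos = (taus[:, None] + (k[None, :] / Lc) * ss[:, None]) * Lq
    pos = np.clip(pos, 0.0, Lq - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, Lq - 1)
    frac = pos - i0
    warped = q[:, i0] * (1.0 - frac) + q[:, i1] * frac  # D x P x Lc

    w = 1.0 + hamming(Lc, sym=True)
    diff = warped - tpl[:, None, :]
    dist = np.sqrt(np.einsum("dpt,t->p", diff * diff, w))
    pen = np.arctan(np.abs(taus)) + 1.5 * np.arctan(np.abs(ss - 1.0))
    return dist + alpha * pen


def grid_align(
    query: np.ndarray,
    template: np.ndarray,
    alpha: float = 0.0,
    tau_bounds: tuple[float, float] = DEFAULT_TAU_BOUNDS,
    s_bounds: tuple[float, float] = DEFAULT_S_BOUNDS,
    resolution: float = 0.002,
) -> AlignmentParams:
    """Dense grid search over the box — the slow, exhaustive fallback."""
    taus = np.arange(tau_bounds[0], tau_bounds[1] + resolution / 2, resolution)
    ss = np.arange(s_bounds[0], s_bounds[1] + resolution / 2, resolution)
    tt, sg = np.meshgrid(taus, ss, indexing="ij")
    losses = _batch_loss(query, template, tt.ravel(), sg.ravel(), alpha)
    k = int(np.argmin(losses))
    return AlignmentParams(float(tt.ravel()[k]), float(sg.ravel()[k]), float(losses[k]))


def linear_align(
    query: np.ndarray,
    template: np.ndarray,
    alpha: float = 0.0,
    tau_bounds: tuple[float, float] = DEFAULT_TAU_BOUNDS,
    s_bounds: tuple[float, float] = DEFAULT_S_BOUNDS,
    method: str = "sampled",
    coarse: int = 48,
    zoom_stages: int = 4,
    n_basins: int = 10,
) -> AlignmentParams:
    """Find the warp minimizing the penalized alignment loss over the box.

    Deterministic for fixed inputs.  ``method="sampled"`` (default)
    evaluates a dense coarse lattice over the box in one vectorized batch
    (the identity transform is always among the candidates) and then
    iteratively zooms a 9x9 lattice around the best point, shrinking the
    search window each stage; final parameter resolution is roughly
    ``box / coarse / 6**zoom_stages``.  ``method="shgo"`` delegates to
    scipy's simplicial homology global optimizer with a dense-grid fallback
    on failure; ``method="grid"`` is the exhaustive search itself.
    The returned cost never exceeds the identity-transform loss.
    """
    if s_bounds[0] <= 0:
        raise ValueError("s_bounds must be strictly positive")
    if tau_bounds[0] >= tau_bounds[1] or s_bounds[0] >= s_bounds[1]:
        raise ValueError("bounds must be non-empty intervals")
    q, tpl = _as_matrix(query), _as_matrix(template)

    if method == "grid":
        return grid_align(q, tpl, alpha, tau_bounds, s_bounds)

    if method == "shgo":
        def loss_vec(v: np.ndarray) -> float:
            return alignment_loss(q, tpl, AlignmentParams(float(v[0]), float(v[1])), alpha)

        try:
            res = shgo(loss_vec, [tau_bounds, s_bounds], n=128, iters=2,
                       sampling_method="sobol")
            if not res.success:
                raise RuntimeError(res.message)
            tau, s = float(res.x[0]), float(np.clip(res.x[1], *s_bounds))
            return AlignmentParams(tau, s, loss_vec([tau, s]))
        except Exception:
            return grid_align(q, tpl, alpha, tau_bounds, s_bounds, resolution=0.005)

    # sampled: coarse lattice (identity included), then iterative zoom
    # refinement of the best few distinct basins
    taus = np.linspace(tau_bounds[0], tau_bounds[1], coarse)
    ss = np.linspace(s_bounds[0], s_bounds[1], coarse)
    tt, sg = np.meshgrid(taus, ss, indexing="ij")
    cand_t = np.concatenate([tt.ravel(), [0.0]])
    cand_s = np.concatenate([sg.ravel(), [1.0]])
    losses = _batch_loss(q, tpl, cand_t, cand_s, alpha)
    order = np.argsort(losses, kind="stable")

    cell_t = (tau_bounds[1] - tau_bounds[0]) / coarse
    cell_s = (s_bounds[1] - s_bounds[0]) / coarse
    starts: list[tuple[float, float, float]] = []
    for k in order:
        t0, s0 = float(cand_t[k]), float(cand_s[k])
        if any(abs(t0 - a) < 1.6 * cell_t and abs(s0 - b) < 1.6 * cell_s
               for a, b, _ in starts):
            continue
        starts.append((t0, s0, float(losses[k])))
        if len(starts) >= max(1, n_basins):
            break

    best_t, best_s, best_loss = min(starts, key=lambda x: x[2])
    for t0, s0, l0 in starts:
        half_t, half_s = cell_t, cell_s
        cur_t, cur_s, cur_l = t0, s0, l0
        for _ in range(zoom_stages):
            zt = np.clip(np.linspace(cur_t - half_t, cur_t + half_t, 9), *tau_bounds)
            zs = np.clip(np.linspace(cur_s - half_s, cur_s + half_s, 9), *s_bounds)
            ztt, zss = np.meshgrid(zt, zs, indexing="ij")
            zl = _batch_loss(q, tpl, ztt.ravel(), zss.ravel(), alpha)
            k = int(np.argmin(zl))
            if zl[k] < cur_l:
                cur_t, cur_s, cur_l = float(ztt.ravel()[k]), float(zss.ravel()[k]), float(zl[k])
            half_t /= 6.0
            half_s /= 6.0
        if cur_l < best_loss:
            best_t, best_s, best_loss = cur_t, cur_s, cur_l
    return AlignmentParams(best_t, best_s, best_loss)
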