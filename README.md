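# tasc — temporally aligned segmentation and clustering

`tasc` segments a continuous multidimensional behavior recording into
recurring sub-second motifs and clusters the instances, refining both
jointly. It is aimed at computational ethology and clinical movement
analysis, where boundaries must be frame-accurate (e.g. to align neural
recordings to behavior) and repeated executions of the same movement vary
in phase and speed.

The core idea: two renditions of one motif are related by a **linear time
warp** — an offset τ_w and a slope s_w in normalized time,

    x̂(t) = x(τ_w + t·s_w),   t ∈ [0, 1),

fitted by minimizing a center-weighted Euclidean distance to a cluster
template plus a warp penalty α·(arctan|τ_w| + 1.5·arctan|s_w − 1|).
Refinement alternates: score each segment's *temporal neighbors* (start
offset m ∈ M, length change l ∈ L) against its cluster centroid by linear
alignment → select the score-maximal non-overlapping set (exact
weighted-interval-scheduling DP) → warp, re-embed (PCA) and re-cluster
(fuzzy c-means) → reinstate motif-like windows inside large unassigned
gaps → repeat. The fitted (τ_w, s_w) per segment are part of the output
and can be applied to simultaneously recorded data streams.

## Worked example

```python
import tasc
from tasc.config import semi_synthetic_config

lib = tasc.make_motif_library(5, seed=0)                     # 5 motifs, 60-90 frames
ds  = tasc.assemble_signal(lib, n_variants_per_motif=8,
                           noise_sigma=0.01, seed=100)       # ground-truthed recording
cfg = semi_synthetic_config(epochs=10, m_step=2, l_step=2, seed=0)
res = tasc.run_tasc(ds.signal, cfg, truth=ds.truth)
```

Running this (`python examples/refine_segmentation.py`) prints:

```
epoch segments    IoU recall silhouette
    0       15  0.313   0.33      0.512
    1       25  0.506   0.42      0.540
    5       34  0.634   0.55      0.567
    9       40  0.785   0.57      0.525
   10       40  0.784   0.72      0.414
```

Starting from naive 90-frame windows, only 15 of the 40 true motif
instances are captured (mean IoU 0.31, unmatched instances count as 0).
Over ten epochs boundary refinement and gap reassignment recover all 40:
IoU rises to 0.78 and recall — the fraction of true instances found *and*
correctly labeled — from 0.33 to 0.72. Each output segment carries its
fitted warp:

```
[  195,   282) cluster 3 tau=-0.005 s=1.012 cost=0.494
```

i.e. this instance is essentially at the cluster's canonical phase and
speed. The other examples (`examples/align_two_motifs.py`,
`examples/generate_synthetic_data.py`) show warp recovery on a single pair
(errors ~1e-4 on noiseless data) and the generator's output.

## Command line

The same pipeline is scriptable from a shell:

```
tasc synth --out data/ --seed 3                  # ground-truthed dataset
tasc run --signal data/signal.csv --truth data/truth.csv \
         --config cfg.yaml --out run/            # refinement + metric trace
tasc evaluate --pred run/segments.csv --truth data/truth.csv --out eval/
```

Signals are CSV (frames as rows, header of feature names) or `.npy`;
segment lists are CSV with columns `start,end,label,score,tau_w,s_w,cost`
(only `start,end` required on input, so initializations exported from
other frameworks drop in via `--init`). Configs are YAML/JSON with the
standard parameter names (`M`, `L`, `alpha`, `gamma`, `centroid_method`,
`centroid_existing`, ...); `L: semi-synthetic` selects the worked schedule
L(n) = (−n, 10) with α = 10^R(n), R from 0.5 to −1. Every run writes a
manifest (config snapshot, input digests, seeds) sufficient to reproduce
its outputs exactly.

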