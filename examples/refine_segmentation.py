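"""Run the full iterative refinement on a ground-truthed recording.

Starts from naive overlapping 90-frame windows, then alternates alignment-
based boundary refinement, overlap elimination, re-clustering and gap
recovery for ten epochs, printing the evaluation metrics per epoch.  Mean
IoU against the ground truth rises steadily and recall grows as gap
reassignment reinstates motifs the naive initialization missed; the
silhouette typically improves as clusters tighten, though it can dip in an
epoch where freshly recovered, not-yet-refined segments join the pool.
"""

import tasc
from tasc.config import semi_synthetic_config

lib = tasc.make_motif_library(5, seed=0)
ds = tasc.assemble_signal(lib, n_variants_per_motif=8, noise_sigma=0.01, seed=100)
print(f"{ds.signal.n_frames} frames, {len(ds.truth.segments)} true motif instances\n")

config = semi_synthetic_config(epochs=10, m_step=2, l_step=2, seed=0)
result = tasc.run_tasc(ds.signal, config, truth=ds.truth)

print(f"{'epoch':>5} {'segments':>8} {'IoU':>6} {'recall':>6} {'silhouette':>10}")
for row in result.metrics:
    print(
        f"{row['epoch']:>5} {row['n_segments']:>8} {row['iou_vs_truth']:>6.3f} "
        f"{row['recall_vs_truth']:>6.2f} {row['silhouette']:>10.3f}"
    )

first, last = result.metrics[0], result.metrics[-1]
print(
    f"\nIoU {first['iou_vs_truth']:.3f} -> {last['iou_vs_truth']:.3f}; "
    f"recall {first['recall_vs_truth']:.2f} -> {last['recall_vs_truth']:.2f}; "
    f"silhouette {first['silhouette']:.3f} -> {last['silhouette']:.3f}"
)
print("Each selected segment carries its fitted warp (tau, s) and alignment cost:")
for s in result.state.segments[:3]:
    print(f"  [{s.start:5d}, {s.end:5d}) cluster {s.label} "
          f"tau={s.align.tau_w:+.3f} s={s.align.s_w:.3f} cost={s.align.cost:.3f}")
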