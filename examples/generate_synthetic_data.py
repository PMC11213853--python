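"""Generate a ground-truthed semi-synthetic behavior recording.

Five synthetic motifs (60-90 frames, five features) are each replicated
eight times under random linear warps (tau ~ U(-0.1, 0.1), s ~ U(0.8, 1.2)),
shuffled, laid on a constant baseline with rest gaps, normalized to [0, 1]
and overlaid with Gaussian noise (sigma = 0.01) — with every true boundary,
label and warp draw retained.
"""

import numpy as np

from tasc import assemble_signal, make_motif_library

library = make_motif_library(n_motifs=5, length_range=(60, 90), n_features=5, seed=0)
print("motif lengths (frames):", [m.shape[1] for m in library.motifs])

ds = assemble_signal(library, n_variants_per_motif=8, noise_sigma=0.01, seed=100)
sig, truth = ds.signal, ds.truth
print(f"signal: {sig.n_features} features x {sig.n_frames} frames at {sig.frame_rate:.0f} fps")
print(f"ground truth: {len(truth.segments)} motif instances in {truth.n_classes} classes")

lengths = [s.length for s in truth.segments]
print(f"instance durations: {min(lengths)}-{max(lengths)} frames "
      f"(warping makes slow renditions longer)")
taus = [p.tau_w for p in ds.warp_record]
ss = [p.s_w for p in ds.warp_record]
print(f"recorded warp draws: tau in [{min(taus):+.3f}, {max(taus):+.3f}], "
      f"s in [{min(ss):.3f}, {max(ss):.3f}]")
print("first five true segments (start, end, motif):")
for s in truth.segments[:5]:
    print(f"  [{s.start:5d}, {s.end:5d})  motif {s.label}")
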