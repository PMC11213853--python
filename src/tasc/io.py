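"""File formats: signal CSV / .npy, segment CSV, metric traces, manifests.

Signals travel as CSV with frames as rows and a header of feature names
(or as dense ``.npy`` arrays, features x frames); the frame rate comes from
the config or a ``<file>.meta.json`` sidecar.  Segment lists are header-ful
CSV with columns ``start,end,label,score,tau_w,s_w,cost`` — the last four
optional on input, so external initializations need only boundaries and
labels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ContinuousSignal
from .segments import UNASSIGNED, AlignmentParams, Segment

__all__ = [
    "read_signal",
    "write_signal",
    "read_segments",
    "write_segments",
    "write_metrics",
    "write_manifest",
    "file_digest",
]


def read_signal(path: str | Path, frame_rate: float | None = None) -> ContinuousSignal:
    path = Path(path)
    meta = path.with_suffix(path.suffix + ".meta.json")
    if frame_rate is None and meta.exists():
        frame_rate = json.loads(meta.read_text()).get("frame_rate")
    if frame_rate is None:
        frame_rate = 30.0
    if path.suffix == ".npy":
        values = np.load(path)
        return ContinuousSignal(np.atleast_2d(values), frame_rate=float(frame_rate))
    df = pd.read_csv(path)
    return ContinuousSignal(
        df.to_numpy(dtype=float).T,
        frame_rate=float(frame_rate),
        feature_names=[str(c) for c in df.columns],
    )


def write_signal(signal: ContinuousSignal, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(signal.values.T, columns=signal.feature_names)
    df.to_csv(path, index=False)
    meta = path.with_suffix(path.suffix + ".meta.json")
    meta.write_text(json.dumps({"frame_rate": signal.frame_rate}))


def read_segments(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path)
    required = {"start", "end"}
    if not required.issubset(df.columns):
        missing = required - set(df.columns)
        raise ValueError(f"segment CSV {path} missing columns: {sorted(missing)}")
    segments = []
    for i, row in df.iterrows():
        try:
            align = None
            if "tau_w" in df.columns and pd.notna(row.get("tau_w")):
                align = AlignmentParams(
                    float(row["tau_w"]),
                    float(row["s_w"]),
                    float(row["cost"]) if "cost" in df.columns and pd.notna(row.get("cost")) else 0.0,
                )
            label = int(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else UNASSIGNED
            score = float(row["score"]) if "score" in df.columns and pd.notna(row.get("score")) else None
            segments.append(Segment(int(row["start"]), int(row["end"]), label, score, align))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad segment at line {i + 2}: {exc}") from exc
    return segments


def write_segments(segments: list[Segment], path: str | Path) -> None:
    rows = [
        {
            "start": s.start,
            "end": s.end,
            "label": s.label,
            "score": s.score,
            "tau_w": s.align.tau_w if s.align else None,
            "s_w": s.align.s_w if s.align else None,
            "cost": s.align.cost if s.align else None,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["start", "end", "label", "score", "tau_w", "s_w", "cost"]).to_csv(
        path, index=False
    )


def write_metrics(metrics: list[dict], path: str | Path) -> None:
    pd.DataFrame(metrics).to_csv(path, index=False)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: dict, inputs: dict[str, str], extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "tasc_version": __version__,
        "config": config,
        "input_digests": {k: file_digest(v) for k, v in inputs.items() if Path(v).exists()},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
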