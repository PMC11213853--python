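"""YAML/JSON configuration mirroring the framework's parameter table.

Top-level keys use the standard parameter names (``M``, ``L``, ``alpha``,
``gamma``, ``centroid_method``, ``centroid_existing``) plus the documented
engineering knobs of :class:`tasc.refinement.TASCConfig`.  ``L`` accepts a
pair, a list of per-epoch pairs, or the string ``"semi-synthetic"`` to get
the worked schedule L(n) = (-n, 10) with alpha = 10^linspace(0.5, -1).
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

import yaml

from .refinement import TASCConfig, semi_synthetic_schedules

__all__ = ["load_config", "config_to_dict", "semi_synthetic_config"]


def semi_synthetic_config(epochs: int = 10, **overrides) -> TASCConfig:
    """The worked semi-synthetic configuration: M=(-10,10), L(n)=(-n,10),
    alpha=10^R(n) with R from 0.5 to -1, gamma=4, 90-frame windows,
    PCA(10) + 5-cluster FCM with median centroids."""
    L, alpha = semi_synthetic_schedules(epochs)
    base = dict(
        M=(-10, 10), L=L, alpha=alpha, gamma=4.0, epochs=epochs,
        # overlapping naive candidates (stride of window/6) so that every
        # motif phase is covered; overlaps are resolved by the membership-
        # score DP before the first epoch
        window=90, stride=15, n_clusters=5, n_components=10,
        # the worked configuration computes element-wise median centroids
        centroid_method="median", centroid_existing=False,
        # sub-second motifs at 120 fps: smooth the movement-energy trace at
        # 2 Hz; with roughly half the recording at rest, a 0.4 quantile puts
        # the activity threshold between the rest and movement modes
        activity_cutoff_hz=2.0, activity_quantile=0.4,
    )
    base.update(overrides)
    return TASCConfig(**base)


def load_config(path: str | Path | None = None, **overrides) -> TASCConfig:
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    data.update(overrides)

    epochs = int(data.get("epochs", 10))
    if data.get("L") == "semi-synthetic":
        L, alpha = semi_synthetic_schedules(epochs)
        data["L"] = L
        data.setdefault("alpha", alpha)

    for key in ("M", "L", "tau_bounds", "s_bounds", "k_range"):
        if key in data and isinstance(data[key], list) and data[key] and not callable(data[key]):
            if all(isinstance(v, (int, float)) for v in data[key]):
                data[key] = tuple(data[key])
            else:
                data[key] = [tuple(v) for v in data[key]]

    valid = {f.name for f in fields(TASCConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TASCConfig(**data)


def config_to_dict(config: TASCConfig) -> dict:
    out = {}
    for f in fields(TASCConfig):
        v = getattr(config, f.name)
        if callable(v):
            v = f"<callable {getattr(v, '__name__', 'L')}>"
        out[f.name] = v
    return out
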