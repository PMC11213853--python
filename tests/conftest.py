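import numpy as np
import pytest

from tasc.preprocess import ContinuousSignal
from tasc.segments import Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_signal():
    """Three features over 100 frames: ramp, sine, constant."""
    t = np.arange(100, dtype=float)
    values = np.vstack([t, np.sin(2 * np.pi * t / 25), np.full(100, 5.0)])
    return ContinuousSignal(values, frame_rate=30.0, feature_names=["ramp", "sine", "const"])


@pytest.fixture
def block_signal():
    """Flat baseline with one high-motion block at frames [200, 300)."""
    T = 500
    values = np.zeros((2, T))
    t = np.arange(100)
    values[0, 200:300] = np.sin(2 * np.pi * t / 10)
    values[1, 200:300] = np.cos(2 * np.pi * t / 14)
    return ContinuousSignal(values, frame_rate=30.0)


def make_segments(intervals, labels=None):
    labels = labels if labels is not None else [-1] * len(intervals)
    return [Segment(a, b, label=l) for (a, b), l in zip(intervals, labels)]
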