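"""The Segment container shared across the pipeline.

Frame intervals are 0-based and half-open ``[start, end)``, so
``length == end - start`` and two segments overlap iff
``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

UNASSIGNED = -1


@dataclass
class AlignmentParams:
    """A linear time warp: offset ``tau_w`` and slope ``s_w``.

    Both parameters live in the normalized t in [0, 1) domain of the query
    sequence; ``tau_frames(query_length)`` converts the offset to frames.
    ``cost`` is the (penalized) alignment loss at these parameters.
    """

    tau_w: float
    s_w: float
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.s_w <= 0:
            raise ValueError("warp slope s_w must be positive")

    def tau_frames(self, query_length: int) -> float:
        return self.tau_w * query_length


IDENTITY_PARAMS = AlignmentParams(0.0, 1.0, 0.0)


@dataclass
class Segment:
    start: int
    end: int
    label: int = UNASSIGNED
    score: Optional[float] = None
    align: Optional[AlignmentParams] = None

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid segment interval [{self.start}, {self.end})")
        if self.length < 2:
            raise ValueError("segments must span at least 2 frames")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Segment") -> bool:
        return self.start < other.end and other.start < self.end

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def assert_nonoverlapping(segments) -> None:
    ordered = sorted(segments, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end > b.start:
            raise ValueError(f"segments overlap: [{a.start},{a.end}) and [{b.start},{b.end})")
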