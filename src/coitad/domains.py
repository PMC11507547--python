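"""Converting per-bin cluster labels into classified diagonal segments.

Consecutive bins with the same cluster label are merged into maximal runs
(noise runs stay separate), then each segment is classified:

* **gap** — the intra-segment submatrix is entirely zero (unmappable bins);
* **tad** — a non-gap segment at least the minimum TAD length (180 kb by
  established estimates of the smallest domains, so ceil(180 / resolution)
  bins — the ceiling guarantees a called TAD never spans less than 180 kb);
* **boundary** — a non-gap segment shorter than the minimum TAD length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np

from .clustering import ClusterLabels
from .errors import IntegrityError
from .io import ContactMatrix

Category = Literal["gap", "tad", "boundary"]

DEFAULT_MIN_TAD_KB = 180


def min_tad_bins(resolution_kb: int, min_tad_kb: int = DEFAULT_MIN_TAD_KB) -> int:
    """Smallest TAD size in bins: ceil(min TAD span / resolution)."""
    if resolution_kb <= 0 or min_tad_kb <= 0:
        raise ValueError("resolution_kb and min_tad_kb must be positive")
    return math.ceil(min_tad_kb / resolution_kb)


@dataclass
class Segment:
    """An inclusive run [start_bin, end_bin] of equally-labeled diagonal bins."""

    start_bin: int
    end_bin: int
    label: int
    category: Optional[Category] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_bin <= self.end_bin):
            raise ValueError(f"invalid segment bounds [{self.start_bin}, {self.end_bin}]")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    def span_kb(self, resolution_kb: int) -> int:
        return self.n_bins * resolution_kb


@dataclass
class DomainCall:
    """Ordered, disjoint segments covering the diagonal, each categorized."""

    segments: List[Segment]
    radius: int
    resolution_kb: int
    min_tad_bins: int

    @property
    def tads(self) -> List[Segment]:
        return [s for s in self.segments if s.category == "tad"]

    def counts(self) -> dict:
        out = {"gap": 0, "tad": 0, "boundary": 0}
        for s in self.segments:
            out[s.category] += 1
        return out


def segments_from_labels(labels: ClusterLabels | Sequence[int] | np.ndarray) -> List[Segment]:
    """Run-length encode a label sequence into maximal equal-label segments."""
    if isinstance(labels, ClusterLabels):
        seq = labels.labels
    else:
        seq = np.asarray(labels, dtype=int)
    if len(seq) == 0:
        raise ValueError("label sequence is empty")
    segments: List[Segment] = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            segments.append(Segment(start_bin=start, end_bin=i - 1, label=int(seq[start])))
            start = i
    return segments


def classify_segments(
    segments: Sequence[Segment],
    matrix: ContactMatrix,
    min_bins: int,
    radius: int = 0,
) -> DomainCall:
    """Tag each segment gap / tad / boundary (gap tested first).

    The gap test inspects the full intra-segment submatrix: a segment whose
    bins show zero contact everywhere within itself is unmappable.
    """
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    n = matrix.n_bins
    pos = 0
    for seg in segments:
        if seg.start_bin != pos:
            raise IntegrityError(
                f"segments do not partition the diagonal: expected start {pos}, "
                f"got {seg.start_bin}"
            )
        pos = seg.end_bin + 1
    if pos != n:
        raise IntegrityError(f"segments cover bins 0..{pos - 1}, matrix has {n} bins")

    classified: List[Segment] = []
    for seg in segments:
        sub = matrix.values[seg.start_bin : seg.end_bin + 1, seg.start_bin : seg.end_bin + 1]
        if not sub.any():
            category: Category = "gap"
        elif seg.n_bins >= min_bins:
            category = "tad"
        else:
            category = "boundary"
        classified.append(
            Segment(seg.start_bin, seg.end_bin, seg.label, category=category)
        )
    return DomainCall(
        segments=classified,
        radius=radius,
        resolution_kb=matrix.resolution_kb,
        min_tad_bins=min_bins,
    )
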