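"""Measure of Concordance (MoC) between two domain partitions.

With partitions A (N_A domains) and B (N_B domains) over the same bins, and
F_ij the number of bins shared by A's i-th and B's j-th domain,

    MoC(A, B) = ( sum_ij F_ij^2 / (|a_i| * |b_j|) - 1 ) / ( sqrt(N_A N_B) - 1 )

with the convention MoC = 1 when N_A = N_B = 1.  MoC is symmetric, lies in
[0, 1], and equals 1 exactly for identical partitions.  Bins not covered by
any domain (gaps, boundary regions) are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple


@dataclass(frozen=True)
class Partition:
    """Sorted, non-overlapping inclusive (start_bin, end_bin) domains."""

    domains: Tuple[Tuple[int, int], ...]
    n_bins: int

    def __init__(self, domains: Sequence[Tuple[int, int]], n_bins: int):
        doms = tuple((int(s), int(e)) for s, e in domains)
        for s, e in doms:
            if not (0 <= s <= e < n_bins):
                raise ValueError(f"domain ({s}, {e}) outside [0, {n_bins})")
        for (s1, e1), (s2, e2) in zip(doms, doms[1:]):
            if s2 <= e1:
                raise ValueError(f"domains overlap or are unsorted: ({s1},{e1}), ({s2},{e2})")
        object.__setattr__(self, "domains", doms)
        object.__setattr__(self, "n_bins", int(n_bins))

    def __len__(self) -> int:
        return len(self.domains)


def moc(a: Partition, b: Partition) -> float:
    """Measure of Concordance between two partitions of the same bin range."""
    if a.n_bins != b.n_bins:
        raise ValueError(f"partitions disagree on bin count: {a.n_bins} vs {b.n_bins}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("MoC is undefined for an empty partition")
    if len(a) == 1 and len(b) == 1:
        return 1.0
    total = 0.0
    for s1, e1 in a.domains:
        for s2, e2 in b.domains:
            overlap = min(e1, e2) - max(s1, s2) + 1
            if overlap > 0:
                total += overlap * overlap / ((e1 - s1 + 1) * (e2 - s2 + 1))
    value = (total - 1.0) / (math.sqrt(len(a) * len(b)) - 1.0)
    return min(1.0, max(0.0, value))


def boundaries(p: Partition) -> List[int]:
    """Domain boundary bin indices: each domain's start and end+1."""
    out: set[int] = set()
    for s, e in p.domains:
        out.add(s)
        out.add(e + 1)
    return sorted(out)


def shared_boundaries(a: Partition, b: Partition, tolerance: int = 0) -> int:
    """Count of a's boundaries with some boundary of b within +/- tolerance."""
    bb = boundaries(b)
    return sum(
        1 for x in boundaries(a) if any(abs(x - y) <= tolerance for y in bb)
    )
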