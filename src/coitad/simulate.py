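"""Synthetic Hi-C matrices with planted ground-truth TADs.

The generator emulates the structure a TAD caller actually sees in a raw
single-chromosome contact map:

* a distance-decaying background ``base / (1 + alpha * |i - j|)``;
* square blocks of elevated contact on the diagonal — the planted TADs.
  Block intensities follow an alternating weak/strong ladder around
  ``intra_level`` (span ``1 +/- intra_spread``): real domains differ in
  contact enrichment, and perfectly identical blocks would make interior
  bins of different domains exact duplicates in feature space, a degenerate
  input no real matrix produces;
* Poisson count sampling at a configurable sequencing ``depth`` (expected
  counts = depth * signal, reported as counts / depth): raw Hi-C is integer
  counts, so shot noise is present even at noise level 0;
* additive symmetrized half-normal noise of scale ``noise_level`` — the
  graded noise dial (levels 4, 8, 12, 16, 20 span easy to hard relative to
  the default ``intra_level`` of 20);
* unmappable bins (``gap_bins``) zeroed in row and column after everything
  else — bins with no reads stay empty at every noise level.

The planted partition depends only on the layout, never on the seed, so two
seeds at the same spec give different matrices with identical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .concordance import Partition
from .errors import ConfigurationError
from .io import ContactMatrix


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one simulated chromosome."""

    n_bins: int
    tad_sizes_bins: Tuple[int, ...]
    resolution_kb: int = 40
    background_decay: float = 0.5
    base_level: float = 10.0
    intra_level: float = 20.0
    intra_spread: float = 0.3
    noise_level: float = 0.0
    depth: Optional[float] = 2.0
    gap_bins: Tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tad_sizes_bins", tuple(int(s) for s in self.tad_sizes_bins))
        object.__setattr__(self, "gap_bins", tuple(int(g) for g in self.gap_bins))
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if any(s < 1 for s in self.tad_sizes_bins):
            raise ConfigurationError("block sizes must be positive")
        if self.intra_level <= 0 or self.base_level <= 0:
            raise ConfigurationError("intra_level and base_level must be positive")
        if self.background_decay <= 0:
            raise ConfigurationError("background_decay must be positive")
        if self.noise_level < 0:
            raise ConfigurationError("noise_level must be >= 0")
        if not (0.0 <= self.intra_spread < 1.0):
            raise ConfigurationError("intra_spread must be in [0, 1)")
        if any(not (0 <= g < self.n_bins) for g in self.gap_bins):
            raise ConfigurationError("gap_bins outside matrix")


def _block_levels(spec: SimSpec) -> np.ndarray:
    """Alternating weak/strong intensity ladder centered on intra_level."""
    k = len(spec.tad_sizes_bins)
    if k == 0:
        return np.empty(0)
    if k == 1:
        return np.array([spec.intra_level])
    ladder = spec.intra_level * np.linspace(1 - spec.intra_spread, 1 + spec.intra_spread, k)
    levels = np.empty(k)
    levels[0::2] = ladder[: (k + 1) // 2]
    levels[1::2] = ladder[::-1][: k // 2]
    return levels


def _place_blocks(spec: SimSpec) -> List[Tuple[int, int]]:
    """Tile blocks left-to-right into the contiguous non-gap stretches."""
    gap = np.zeros(spec.n_bins, dtype=bool)
    gap[list(spec.gap_bins)] = True
    placements: List[Tuple[int, int]] = []
    pos = 0
    for size in spec.tad_sizes_bins:
        # advance to the next stretch of `size` consecutive non-gap bins
        while True:
            while pos < spec.n_bins and gap[pos]:
                pos += 1
            end = pos + size
            if end > spec.n_bins:
                raise ConfigurationError(
                    f"infeasible layout: block of {size} bins does not fit "
                    f"(position {pos} of {spec.n_bins})"
                )
            if gap[pos:end].any():
                pos = pos + int(np.argmax(gap[pos:end])) + 1
                continue
            placements.append((pos, end - 1))
            pos = end
            break
    return placements


def simulate_hic(spec: SimSpec) -> Tuple[ContactMatrix, Partition]:
    """Generate one matrix and its planted ground-truth partition."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    idx = np.arange(n)
    signal = spec.base_level / (1.0 + spec.background_decay * np.abs(idx[:, None] - idx[None, :]))
    blocks = _place_blocks(spec)
    for (start, end), level in zip(blocks, _block_levels(spec)):
        signal[start : end + 1, start : end + 1] += level

    if spec.depth:
        counts = rng.poisson(spec.depth * signal).astype(float) / spec.depth
        matrix = np.triu(counts) + np.triu(counts, 1).T
    else:
        matrix = signal.copy()

    if spec.noise_level > 0:
        noise = np.abs(rng.normal(0.0, spec.noise_level, (n, n)))
        matrix += (noise + noise.T) / 2.0

    np.clip(matrix, 0.0, None, out=matrix)
    if spec.gap_bins:
        gaps = list(spec.gap_bins)
        matrix[gaps, :] = 0.0
        matrix[:, gaps] = 0.0

    truth = Partition(blocks, n_bins=n)
    cm = ContactMatrix(values=matrix, resolution_kb=spec.resolution_kb, chrom="chrSim")
    return cm, truth


#: Canonical benchmark layout: a 200-bin two-arm chromosome at 40 kb with a
#: 3-bin leading telomere gap, five domains per arm, a 20-bin centromeric
#: gap, and an 11-bin trailing telomere gap.
BENCHMARK_ARM1 = (20, 16, 18, 14, 17)
BENCHMARK_ARM2 = (19, 15, 18, 13, 16)


def benchmark_spec(noise_level: float = 0.0, seed: int = 0, n_bins: int = 200) -> SimSpec:
    """The standard two-arm study condition used by the test benchmarks."""
    if n_bins != 200:
        raise ConfigurationError("the benchmark layout is defined for 200 bins")
    arm1 = sum(BENCHMARK_ARM1)  # 85
    gaps = tuple(range(0, 3)) + tuple(range(3 + arm1, 3 + arm1 + 20)) + tuple(range(189, 200))
    return SimSpec(
        n_bins=n_bins,
        tad_sizes_bins=BENCHMARK_ARM1 + BENCHMARK_ARM2,
        gap_bins=gaps,
        noise_level=noise_level,
        seed=seed,
    )
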