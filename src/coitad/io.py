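"""Reading and writing Hi-C contact matrices and domain calls.

Supported input dialects:

* dense whitespace-delimited N x N text (one matrix row per line);
* sparse "i j value" triplets with 0-based (default) or 1-based bin indices.

Domain calls are written as a BED file (0-based half-open genomic
coordinates) plus a two-column bin-index file listing TAD segments only,
the format consumed by most domain-list tools.

Coordinate conventions: bins are 0-based; segments are inclusive
``[start_bin, end_bin]``; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError, IntegrityError, RangeError, ShapeError

logger = logging.getLogger("coitad")

#: Relative tolerance above which an input matrix is considered asymmetric
#: and gets symmetrized by averaging with its transpose.
SYMMETRY_RTOL = 1e-6


@dataclass
class ContactMatrix:
    """A symmetric, non-negative bin-level Hi-C contact matrix.

    Parameters
    ----------
    values
        N x N array of contact frequencies.
    resolution_kb
        Bin size in kilobases.
    chrom
        Optional chromosome label carried through to output files.
    """

    values: np.ndarray
    resolution_kb: int
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError(f"contact matrix must be square, got {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ShapeError("contact matrix needs at least 2 bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contact matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("contact matrix contains negative entries")
        if self.resolution_kb <= 0:
            raise ValueError("resolution_kb must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def _symmetrize(values: np.ndarray) -> np.ndarray:
    """Average with the transpose when asymmetry exceeds SYMMETRY_RTOL."""
    scale = max(np.abs(values).max(), 1.0)
    asym = np.abs(values - values.T).max()
    if asym > SYMMETRY_RTOL * scale:
        logger.warning(
            "input matrix asymmetric (max |M - M^T| = %.3g); symmetrizing as (M + M^T)/2",
            asym,
        )
        return (values + values.T) / 2.0
    return values


def read_dense_matrix(
    path: str | Path, resolution_kb: int, chrom: Optional[str] = None
) -> ContactMatrix:
    """Load a dense whitespace-delimited N x N contact matrix.

    NaN entries (unmappable bins) are replaced by 0.  Asymmetric input is
    symmetrized by averaging, with a logged warning.
    """
    try:
        values = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse dense matrix {path}: {exc}") from exc
    if values.shape[0] != values.shape[1]:
        raise ShapeError(
            f"dense matrix must be square, got {values.shape[0]}x{values.shape[1]}"
        )
    if values.shape[0] < 2:
        raise ShapeError("contact matrix needs at least 2 bins")
    values = np.nan_to_num(values, nan=0.0)
    if np.any(values < 0):
        raise ValueError("contact matrix contains negative entries")
    values = _symmetrize(values)
    return ContactMatrix(values=values, resolution_kb=resolution_kb, chrom=chrom)


def write_dense_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    """Write a dense matrix in the whitespace-delimited dialect."""
    np.savetxt(path, matrix.values, fmt="%.10g")


def read_sparse_triplets(
    path: str | Path,
    n_bins: int,
    resolution_kb: int,
    one_based: bool = False,
    chrom: Optional[str] = None,
) -> ContactMatrix:
    """Load "i j value" triplets into a dense symmetric matrix.

    Unlisted cells are zero; each listed (i, j) also fills (j, i).  Duplicate
    entries must agree in value.
    """
    offset = 1 if one_based else 0
    values = np.zeros((n_bins, n_bins), dtype=float)
    seen = np.zeros((n_bins, n_bins), dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'i j value', got {len(parts)} fields"
                )
            try:
                i, j, v = int(parts[0]) - offset, int(parts[1]) - offset, float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise RangeError(
                    f"{path}:{lineno}: bin index ({i}, {j}) outside [0, {n_bins})"
                )
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative contact value {v}")
            for a, b in {(i, j), (j, i)}:
                if seen[a, b] and values[a, b] != v:
                    raise ValueError(
                        f"{path}:{lineno}: conflicting duplicate for ({i}, {j}): "
                        f"{values[a, b]} vs {v}"
                    )
                values[a, b] = v
                seen[a, b] = True
    return ContactMatrix(values=values, resolution_kb=resolution_kb, chrom=chrom)


# write_domains / read_domain_bins operate on the DomainCall type defined in
# coitad.domains; imported lazily to keep the module dependency graph acyclic.


def write_domains(call, resolution_kb: int, chrom: str, path: str | Path) -> Tuple[Path, Path]:
    """Write a domain call as ``<path>.bed`` and ``<path>.domains``.

    The BED file lists every segment (chrom, chromStart, chromEnd, category)
    in 0-based half-open coordinates with start = start_bin * resolution_kb
    * 1000.  The ``.domains`` file lists inclusive (start_bin, end_bin) pairs
    for TAD segments only.
    """
    segments = call.segments
    for prev, cur in zip(segments, segments[1:]):
        if cur.start_bin <= prev.end_bin:
            raise IntegrityError(
                f"segments unordered or overlapping: {prev} then {cur}"
            )
    path = Path(path)
    bed_path = path.with_suffix(path.suffix + ".bed")
    dom_path = path.with_suffix(path.suffix + ".domains")
    bp = resolution_kb * 1000
    with open(bed_path, "w") as bed:
        bed.write("#chrom\tchromStart\tchromEnd\tname\n")
        for seg in segments:
            bed.write(
                f"{chrom}\t{seg.start_bin * bp}\t{(seg.end_bin + 1) * bp}\t{seg.category}\n"
            )
    with open(dom_path, "w") as dom:
        dom.write("#start_bin\tend_bin\n")
        for seg in segments:
            if seg.category == "tad":
                dom.write(f"{seg.start_bin}\t{seg.end_bin}\n")
    return bed_path, dom_path


def read_domain_bins(path: str | Path) -> List[Tuple[int, int]]:
    """Parse a two-column bin-index domain file back into (start, end) pairs."""
    domains: List[Tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'start_bin end_bin', got {line!r}"
                )
            s, e = int(parts[0]), int(parts[1])
            if e < s:
                raise FormatError(f"{path}:{lineno}: end_bin {e} < start_bin {s}")
            domains.append((s, e))
    return domains
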