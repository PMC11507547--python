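"""Circle-of-influence feature extraction.

For every bin *i* on the matrix diagonal, the circle of influence (COI) at
radius *r* is the neighborhood of cells within *r* of the diagonal cell
(i, i), flattened into a fixed-length feature vector.  The semi-circle
variant keeps only the half of the neighborhood on or above the main
diagonal (offsets with ``col_offset >= row_offset``), removing the mirror
redundancy of a symmetric matrix.

Two neighborhood geometries are provided: ``euclidean_disk`` (cells with
``di^2 + dj^2 <= r^2``, the default) and ``chebyshev_square`` (the full
``(2r+1) x (2r+1)`` window).  Cells falling outside the matrix contribute a
pad value of 0, so every bin yields a vector of the same length.

The enumeration order within a mask follows the compass listing used to
describe the feature (top-left, top-center, top-right, right, center, left,
bottom-left, bottom-center, bottom-right for the circle; the semi-circle
lists its row-0 cells center-first).  Pairwise Euclidean distances between
feature vectors — and hence the clustering — are invariant to this order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .io import ContactMatrix

logger = logging.getLogger("coitad")

Shape = Literal["circle", "semicircle"]
Geometry = Literal["euclidean_disk", "chebyshev_square"]

MIN_RADIUS = 2
DEFAULT_MAX_TAD_SIZE_KB = 800


def max_radius(resolution_kb: int, max_tad_size_kb: int = DEFAULT_MAX_TAD_SIZE_KB) -> int:
    """Largest COI radius: floor(max TAD size / resolution).

    The cap keeps the neighborhood from reaching past the largest plausible
    domain; 800 kb is the conventional upper bound on TAD span.
    """
    if resolution_kb <= 0 or max_tad_size_kb <= 0:
        raise ValueError("resolution_kb and max_tad_size_kb must be positive")
    r = max_tad_size_kb // resolution_kb
    if r < MIN_RADIUS:
        raise ConfigurationError(
            f"resolution {resolution_kb} kb too coarse for max TAD size "
            f"{max_tad_size_kb} kb (max radius {r} < {MIN_RADIUS})"
        )
    return r


@dataclass(frozen=True)
class RadiusSchedule:
    """The ordered list of radii evaluated by the pipeline (2 .. max radius)."""

    min_radius: int
    max_radius: int

    def __post_init__(self) -> None:
        if self.max_radius < self.min_radius:
            raise ConfigurationError(
                f"max_radius {self.max_radius} < min_radius {self.min_radius}"
            )

    @property
    def radii(self) -> List[int]:
        return list(range(self.min_radius, self.max_radius + 1))


def radius_schedule(
    resolution_kb: int, max_tad_size_kb: int = DEFAULT_MAX_TAD_SIZE_KB
) -> RadiusSchedule:
    return RadiusSchedule(MIN_RADIUS, max_radius(resolution_kb, max_tad_size_kb))


@dataclass(frozen=True)
class OffsetMask:
    """The (row_offset, col_offset) cells read around each diagonal bin."""

    radius: int
    shape: Shape
    geometry: Geometry
    offsets: Tuple[Tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.offsets)


def _in_geometry(di: int, dj: int, radius: int, geometry: Geometry) -> bool:
    if geometry == "euclidean_disk":
        # the innermost ring is always the full 8-cell compass neighborhood
        # (the documented radius-1 feature); the disk predicate applies beyond
        return di * di + dj * dj <= max(radius * radius, 2)
    if geometry == "chebyshev_square":
        return max(abs(di), abs(dj)) <= radius
    raise ValueError(f"unknown geometry {geometry!r}")


def build_mask(radius: int, shape: Shape = "circle", geometry: Geometry = "euclidean_disk") -> OffsetMask:
    """Enumerate the COI offsets for one radius.

    Circle: rows top to bottom; within each row columns left to right,
    except row 0 which runs right to left so the sequence reads
    ... top-right, right, center, left, bottom-left ...  Semi-circle: the
    offsets with ``dj >= di`` (on or above the main diagonal), rows top to
    bottom, columns left to right, so row 0 reads center, right.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if shape not in ("circle", "semicircle"):
        raise ValueError(f"unknown shape {shape!r}")
    offsets: List[Tuple[int, int]] = []
    for di in range(-radius, radius + 1):
        cols = range(-radius, radius + 1)
        if di == 0 and shape == "circle":
            cols = range(radius, -radius - 1, -1)
        for dj in cols:
            if not _in_geometry(di, dj, radius, geometry):
                continue
            if shape == "semicircle" and dj < di:
                continue
            offsets.append((di, dj))
    return OffsetMask(radius=radius, shape=shape, geometry=geometry, offsets=tuple(offsets))


@dataclass
class FeatureTable:
    """Per-bin COI feature vectors for one (radius, shape) combination."""

    radius: int
    shape: Shape
    vectors: np.ndarray
    #: set by dim_reduce.pca_project on reduced tables
    explained_variance_ratio: Optional[np.ndarray] = None

    @property
    def n_bins(self) -> int:
        return self.vectors.shape[0]


def build_features(matrix: ContactMatrix, mask: OffsetMask) -> FeatureTable:
    """Extract one feature vector per diagonal bin.

    Row *i* is ``[matrix[i+di, i+dj] for (di, dj) in mask.offsets]`` with
    out-of-matrix cells contributing 0.
    """
    values = matrix.values
    n = matrix.n_bins
    idx = np.arange(n)
    vectors = np.zeros((n, len(mask)), dtype=float)
    for k, (di, dj) in enumerate(mask.offsets):
        rows = idx + di
        cols = idx + dj
        valid = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
        vectors[valid, k] = values[rows[valid], cols[valid]]
    return FeatureTable(radius=mask.radius, shape=mask.shape, vectors=vectors)


def build_all_features(
    matrix: ContactMatrix,
    schedule: RadiusSchedule,
    shape: Shape = "semicircle",
    geometry: Geometry = "euclidean_disk",
    out_dir: Optional[str | Path] = None,
) -> Dict[int, FeatureTable]:
    """Build one FeatureTable per radius in the schedule.

    When ``out_dir`` is given, each table is also written as a tab-separated
    file ``feat_r<radius>_<shape>.tsv`` (one bin per row).
    """
    tables: Dict[int, FeatureTable] = {}
    for r in schedule.radii:
        mask = build_mask(r, shape=shape, geometry=geometry)
        table = build_features(matrix, mask)
        logger.debug("radius %d: %d-cell %s mask -> vectors %s", r, len(mask), shape, table.vectors.shape)
        tables[r] = table
        if out_dir is not None:
            out_path = Path(out_dir) / f"feat_r{r}_{shape}.tsv"
            np.savetxt(out_path, table.vectors, fmt="%.10g", delimiter="\t")
    return tables
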