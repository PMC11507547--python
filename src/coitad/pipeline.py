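"""End-to-end orchestration: features per radius -> (PCA) -> clustering ->
domain calling -> quality scoring -> best-radius selection.

The defaults reproduce the recommended configuration: semi-circle features
on a Euclidean disk, no dimension reduction, radii from 2 up to the 800 kb
cap, minimum TAD span 180 kb, and ``min_cluster_size`` tied to the minimum
TAD size in bins.  Every radius's call is retained in the result; the
selected radius is simply the quality argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .clustering import cluster_bins
from .dim_reduce import PCAConfig, pca_project
from .domains import DEFAULT_MIN_TAD_KB, DomainCall, classify_segments, min_tad_bins, segments_from_labels
from .features import (
    DEFAULT_MAX_TAD_SIZE_KB,
    Geometry,
    Shape,
    build_all_features,
    radius_schedule,
)
from .io import ContactMatrix, write_domains
from .quality import QualityReport, evaluate_calls, write_quality_tsv

logger = logging.getLogger("coitad")


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline invocation."""

    shape: Shape = "semicircle"
    geometry: Geometry = "euclidean_disk"
    max_tad_size_kb: int = DEFAULT_MAX_TAD_SIZE_KB
    min_tad_kb: int = DEFAULT_MIN_TAD_KB
    pca: PCAConfig = field(default_factory=PCAConfig)
    min_cluster_size: Optional[int] = None  # default: max(2, min_tad_bins)
    min_samples: Optional[int] = None
    out_dir: Optional[str] = None
    chrom: Optional[str] = None


@dataclass
class PipelineResult:
    report: QualityReport
    calls: Dict[int, DomainCall]

    @property
    def best_radius(self) -> int:
        return self.report.best_radius

    @property
    def best_call(self) -> DomainCall:
        return self.calls[self.best_radius]


def run_pipeline(matrix: ContactMatrix, config: Optional[RunConfig] = None) -> PipelineResult:
    """Run the full caller on one contact matrix.

    Deterministic for fixed input and configuration.  When ``out_dir`` is
    set, writes per-radius domain files (``domains_r<r>.bed/.domains``), the
    quality table (``quality.tsv``), the selected call (``domains_best.*``)
    and, for reference, the per-radius feature tables.
    """
    config = config or RunConfig()
    schedule = radius_schedule(matrix.resolution_kb, config.max_tad_size_kb)
    min_bins = min_tad_bins(matrix.resolution_kb, config.min_tad_kb)
    mcs = config.min_cluster_size if config.min_cluster_size is not None else max(2, min_bins)
    chrom = config.chrom or matrix.chrom or "chr"
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    logger.info(
        "pipeline: N=%d bins at %d kb, radii %d..%d, shape=%s, geometry=%s, "
        "min_tad_bins=%d, min_cluster_size=%d, pca=%s",
        matrix.n_bins, matrix.resolution_kb, schedule.min_radius, schedule.max_radius,
        config.shape, config.geometry, min_bins, mcs,
        f"retention {config.pca.retention}" if config.pca.enabled else "off",
    )

    tables = build_all_features(
        matrix, schedule, shape=config.shape, geometry=config.geometry,
        out_dir=out_dir if out_dir else None,
    )

    calls: Dict[int, DomainCall] = {}
    for r, table in tables.items():
        if config.pca.enabled:
            table = pca_project(table, config.pca.retention)
        labels = cluster_bins(table, min_cluster_size=mcs, min_samples=config.min_samples)
        segments = segments_from_labels(labels)
        call = classify_segments(segments, matrix, min_bins, radius=r)
        counts = call.counts()
        logger.debug(
            "radius %d: %d clusters, %d segments (%d tad / %d boundary / %d gap)",
            r, labels.n_clusters, len(call.segments),
            counts["tad"], counts["boundary"], counts["gap"],
        )
        calls[r] = call
        if out_dir:
            write_domains(call, matrix.resolution_kb, chrom, out_dir / f"domains_r{r}")

    report = evaluate_calls(matrix, calls)
    if out_dir:
        write_quality_tsv(report, out_dir / "quality.tsv")
        write_domains(
            calls[report.best_radius], matrix.resolution_kb, chrom, out_dir / "domains_best"
        )
    return PipelineResult(report=report, calls=calls)
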