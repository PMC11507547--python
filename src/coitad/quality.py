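"""Intra-versus-inter TAD quality scoring and best-radius selection.

For TAD *i*, quality = intra(i) - inter(i, j): the mean contact frequency
inside the TAD's diagonal square minus the mean contact between the TAD and
its adjacent TADs.  ``inter`` is averaged over both existing neighbors in
the ordered TAD list (one term at the chromosome ends; a lone TAD scores its
intra mean).  A radius's overall quality is the arithmetic mean over its
TADs; the radius with the largest overall quality is selected, ties going to
the smallest radius.  Calls with no TAD score -inf so the selection never
returns a degenerate result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .domains import DomainCall, Segment
from .io import ContactMatrix

logger = logging.getLogger("coitad")


def intra_score(matrix: ContactMatrix, tad: Segment) -> float:
    """Mean contact over the TAD's square submatrix."""
    sub = matrix.values[tad.start_bin : tad.end_bin + 1, tad.start_bin : tad.end_bin + 1]
    return float(sub.mean())


def inter_score(matrix: ContactMatrix, tad_i: Segment, tad_j: Segment) -> float:
    """Mean contact over the rectangle between two TADs."""
    if (tad_i.start_bin, tad_i.end_bin) == (tad_j.start_bin, tad_j.end_bin):
        raise ValueError("inter_score needs two distinct TADs")
    sub = matrix.values[
        tad_i.start_bin : tad_i.end_bin + 1, tad_j.start_bin : tad_j.end_bin + 1
    ]
    return float(sub.mean())


def tad_quality(matrix: ContactMatrix, tads: Sequence[Segment], i: int) -> float:
    """intra(i) minus the mean inter to the existing adjacent TADs."""
    intra = intra_score(matrix, tads[i])
    inters = [
        inter_score(matrix, tads[i], tads[j])
        for j in (i - 1, i + 1)
        if 0 <= j < len(tads)
    ]
    if not inters:
        return intra
    return intra - float(np.mean(inters))


def overall_quality(matrix: ContactMatrix, call: DomainCall) -> float:
    """Mean TAD quality of a call; -inf when the call has no TAD."""
    tads = call.tads
    if not tads:
        return float("-inf")
    return float(np.mean([tad_quality(matrix, tads, i) for i in range(len(tads))]))


def select_best_radius(scores: Mapping[int, float]) -> int:
    """Argmax of overall quality; ties broken by the smallest radius."""
    if not scores:
        raise ValueError("no radii evaluated")
    return min(scores, key=lambda r: (-scores[r], r))


@dataclass
class QualityReport:
    """Per-radius quality summary plus the selected best radius."""

    per_radius: Dict[int, float]
    per_tad: Dict[int, List[Tuple[int, float, float, float]]]
    best_radius: int

    def rows(self) -> List[Tuple[int, int, float, bool]]:
        return [
            (r, len(self.per_tad[r]), self.per_radius[r], r == self.best_radius)
            for r in sorted(self.per_radius)
        ]


def evaluate_calls(
    matrix: ContactMatrix, calls: Mapping[int, DomainCall]
) -> QualityReport:
    """Score every radius's call and select the best radius."""
    per_radius: Dict[int, float] = {}
    per_tad: Dict[int, List[Tuple[int, float, float, float]]] = {}
    for r, call in calls.items():
        tads = call.tads
        rows: List[Tuple[int, float, float, float]] = []
        for i in range(len(tads)):
            intra = intra_score(matrix, tads[i])
            q = tad_quality(matrix, tads, i)
            rows.append((i, intra, intra - q, q))
        per_tad[r] = rows
        per_radius[r] = overall_quality(matrix, call)
    best = select_best_radius(per_radius)
    logger.info("selected radius %d (overall quality %.4g)", best, per_radius[best])
    return QualityReport(per_radius=per_radius, per_tad=per_tad, best_radius=best)


def write_quality_tsv(report: QualityReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("radius\tn_tads\toverall_quality\tselected\n")
        for radius, n_tads, q, selected in report.rows():
            fh.write(f"{radius}\t{n_tads}\t{q:.6g}\t{int(selected)}\n")
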