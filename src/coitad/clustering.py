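"""Density-based clustering of per-bin feature vectors.

HDBSCAN builds a minimum spanning tree of the mutual-reachability graph
under the Euclidean metric, condenses it into a cluster hierarchy, and
extracts the most stable clusters; sparse points are labeled noise (-1).
Noise bins are kept as-is: downstream, a maximal run of noise bins forms its
own segment, which is exactly how the sparse stretches between dense
diagonal squares should behave.

``allow_single_cluster`` is enabled so that a feature table with one dense
group (e.g. a matrix that is a single domain) yields one cluster instead of
all-noise.  Cluster ids are relabeled to first-appearance order along the
diagonal so output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.cluster import HDBSCAN

from .errors import ConfigurationError
from .features import FeatureTable

NOISE = -1


@dataclass
class ClusterLabels:
    """One integer label per diagonal bin; -1 marks noise."""

    labels: np.ndarray
    radius: int
    params: Tuple[int, Optional[int]]

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids by first appearance; keep noise at -1."""
    out = np.full_like(labels, NOISE)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_bins(
    features: FeatureTable,
    min_cluster_size: int,
    min_samples: Optional[int] = None,
) -> ClusterLabels:
    """Cluster the feature rows of one radius with HDBSCAN (Euclidean)."""
    if min_cluster_size < 2:
        raise ConfigurationError("min_cluster_size must be >= 2")
    n = features.n_bins
    if n <= min_cluster_size:
        raise ConfigurationError(
            f"need more bins ({n}) than min_cluster_size ({min_cluster_size})"
        )
    model = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        metric="euclidean",
        allow_single_cluster=True,
        copy=True,
    )
    raw = model.fit_predict(features.vectors)
    labels = _relabel_first_appearance(np.asarray(raw, dtype=int))
    return ClusterLabels(labels=labels, radius=features.radius,
                         params=(min_cluster_size, min_samples))
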