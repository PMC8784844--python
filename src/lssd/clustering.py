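"""Spectral clustering of cells on the (diffused, symmetrized) similarity graph.

Normalized-cut variant: rows of the C smallest eigenvectors of the symmetric
normalized Laplacian are unit-normalized and partitioned by k-means
(k-means++ initialization, 25 restarts, fixed seed). Labels are relabeled to
first-appearance order so the output is deterministic given (S, C, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .clusternum import SeparationCostCurve, laplacian_eigenvectors, _normalize_rows

_KMEANS_RESTARTS = 25
_MAX_RESEED = 5


@dataclass
class ClusterSolution:
    """Integer labels in [0, C) plus the parameters that produced them."""

    labels: np.ndarray
    C: int
    seed: int
    curve: SeparationCostCurve | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not (0 <= self.labels.min() and self.labels.max() < self.C):
            raise ValueError("labels must lie in [0, C)")


def relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map labels so cluster ids appear in order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def spectral_cluster(S_sym: np.ndarray, C: int, seed: int = 0) -> ClusterSolution:
    """Assign C cluster labels on a symmetric non-negative similarity matrix."""
    S_sym = np.asarray(S_sym, dtype=float)
    n = S_sym.shape[0]
    if C < 2:
        raise ValueError("C must be >= 2")
    if C > n:
        raise ValueError(f"C={C} exceeds number of cells {n}")
    n_comp, _ = connected_components(sp.csr_matrix(S_sym > 0), directed=False)
    if n_comp > C:
        warnings.warn(
            f"similarity graph has {n_comp} connected components > C={C}; "
            "labels may merge disconnected groups",
            RuntimeWarning,
        )
    vecs = laplacian_eigenvectors(S_sym, C)
    emb = _normalize_rows(vecs)
    labels = None
    for attempt in range(_MAX_RESEED):
        km = KMeans(
            n_clusters=C,
            n_init=_KMEANS_RESTARTS,
            random_state=seed + 1000 * attempt,
        )
        labels = km.fit_predict(emb)
        if np.unique(labels).size == C:
            break
        warnings.warn("k-means returned an empty cluster; re-seeding", RuntimeWarning)
    labels = relabel_first_appearance(labels)
    return ClusterSolution(labels=labels, C=C, seed=seed)
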