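"""Clustering-concordance metrics: NMI and the Hubert-Arabie adjusted Rand index.

Both compare an inferred partition against a reference, are symmetric in
their arguments and invariant to label renaming. NMI is normalized by the
arithmetic mean of the two entropies (natural logs). The heavy lifting is
delegated to scikit-learn; this module adds the length/shape contracts and
the contingency-table container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix


def _as_labels(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "labels", x))
    if arr.ndim != 1:
        raise ValueError("label vectors must be one-dimensional")
    return arr


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_labels(a), _as_labels(b)
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("label vectors must be non-empty")
    return a, b


@dataclass
class ContingencyTable:
    """Co-occurrence counts of label pairs between two partitions."""

    counts: np.ndarray
    n: int

    @classmethod
    def from_labels(cls, a, b) -> "ContingencyTable":
        a, b = _check_pair(a, b)
        counts = np.asarray(contingency_matrix(a, b))
        return cls(counts=counts, n=int(a.size))


def nmi(a, b) -> float:
    """Normalized mutual information, I(a;b) / mean(H(a), H(b)), in [0, 1]."""
    a, b = _check_pair(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(a, b) -> float:
    """Hubert-Arabie adjusted Rand index (1 = identical, ~0 = random, can be < 0)."""
    a, b = _check_pair(a, b)
    return float(adjusted_rand_score(a, b))
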