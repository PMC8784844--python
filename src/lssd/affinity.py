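"""Local-scaling (self-tuning) cell-cell affinity.

The affinity between cells i and j is

    W(i, j) = exp(-d^2(x_i, x_j) / (sigma_i * sigma_j)),

where d is the Euclidean distance over genes and sigma_i is the distance
from cell i to its K-th nearest other cell (K = 5 by default). Because
every pairwise distance is divided by the product of the two local scales,
W is invariant to a uniform rescaling of the input coordinates and adapts
to local density: similarities within tight and loose clusters end up on a
comparable scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_matrix import ExpressionMatrix

DEFAULT_K_SCALE = 5


@dataclass
class AffinityGraph:
    """Symmetric local-scaling affinity W with its per-cell scales sigma."""

    W: np.ndarray
    sigma: np.ndarray
    K_scale: int

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]


def pairwise_euclidean(X) -> np.ndarray:
    """Exact symmetric Euclidean distance matrix over the gene dimension."""
    values = X.to_dense() if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if sp.issparse(values):
        values = np.asarray(values.todense(), dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells for pairwise distances")
    sq = np.einsum("ij,ij->i", values, values)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (values @ values.T)
    np.maximum(d2, 0.0, out=d2)
    D = np.sqrt(d2)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def local_scales(D: np.ndarray, K: int = DEFAULT_K_SCALE) -> np.ndarray:
    """Distance from each cell to its K-th nearest other cell.

    Self is excluded from the ranking (its distance is always 0). A zero
    scale — duplicated cells closer than the K-th neighbor — is replaced by
    the smallest positive distance in that row, or by a global epsilon if
    the row is entirely zero, with a warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < number of cells ({n})")
    offdiag = D + np.diag(np.full(n, np.inf))
    sigma = np.partition(offdiag, K - 1, axis=1)[:, K - 1]
    if np.any(sigma <= 0):
        bad = np.flatnonzero(sigma <= 0)
        warnings.warn(
            f"{bad.size} cells have zero local scale (duplicate cells); "
            "falling back to the smallest positive row distance",
            RuntimeWarning,
        )
        eps = 1e-12 * max(D.max(), 1.0)
        for i in bad:
            positive = offdiag[i][np.isfinite(offdiag[i]) & (offdiag[i] > 0)]
            sigma[i] = positive.min() if positive.size else eps
    return sigma


def local_scaling_affinity(D: np.ndarray, sigma: np.ndarray, K_scale: int = DEFAULT_K_SCALE) -> AffinityGraph:
    """W(i, j) = exp(-d^2 / (sigma_i sigma_j)); symmetric, unit diagonal."""
    D = np.asarray(D, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive (repair upstream)")
    W = np.exp(-(D**2) / np.outer(sigma, sigma))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return AffinityGraph(W=W, sigma=sigma, K_scale=K_scale)


def build_affinity(X, K_scale: int = DEFAULT_K_SCALE) -> AffinityGraph:
    """Convenience: distances -> local scales -> affinity in one call."""
    D = pairwise_euclidean(X)
    sigma = local_scales(D, K_scale)
    return local_scaling_affinity(D, sigma, K_scale)
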