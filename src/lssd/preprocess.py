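"""Optional gene filtering and transformation applied before distance computation.

Highly variable genes are ranked by the variance-to-mean ratio (dispersion)
computed on the matrix as read, i.e. on the count scale. Both steps are off
by default: the benchmark pipeline runs on the full unfiltered matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_matrix import ExpressionMatrix


@dataclass
class PreprocessConfig:
    n_top_genes: int | None = None
    log_transform: bool = False
    pseudo_count: float = 1.0


def _gene_moments(values) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and unbiased variance over cells."""
    n = values.shape[0]
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=0)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=0)).ravel()
        var = (sq - mean**2) * n / max(n - 1, 1)
    else:
        mean = values.mean(axis=0)
        var = values.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return mean, var


def gene_dispersion(X: ExpressionMatrix) -> np.ndarray:
    """Variance-to-mean ratio per gene; genes with zero mean get dispersion 0."""
    mean, var = _gene_moments(X.values)
    disp = np.zeros_like(mean)
    nz = mean > 0
    disp[nz] = var[nz] / mean[nz]
    return disp


def select_hvg_vmr(X: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with largest variance-to-mean ratio.

    Invariable genes (zero dispersion) are never selected; ties are broken
    toward the smaller gene index and the original gene order is preserved
    among the kept set.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    disp = gene_dispersion(X)
    n_informative = int(np.count_nonzero(disp > 0))
    if n_top > n_informative:
        raise ValueError(
            f"requested {n_top} highly variable genes but only "
            f"{n_informative} genes have positive dispersion"
        )
    # stable sort on -dispersion: ties keep ascending gene index
    order = np.argsort(-disp, kind="stable")[:n_top]
    keep = np.sort(order)
    values = X.values[:, keep]
    return ExpressionMatrix(values, list(X.cell_ids), [X.gene_ids[i] for i in keep])


def log1p_transform(X: ExpressionMatrix, pseudo_count: float = 1.0) -> ExpressionMatrix:
    """Elementwise log(x + pseudo_count).

    With the default pseudo-count of 1 this is the usual log1p; zeros map to
    zero so sparsity is preserved.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    if (X.values.min() if not sp.issparse(X.values) else X.values.min()) < 0:
        raise ValueError("log transform requires non-negative values")
    if sp.issparse(X.values) and pseudo_count == 1.0:
        values = X.values.copy()
        values.data = np.log1p(values.data)
    else:
        values = np.log(X.to_dense() + pseudo_count)
    return ExpressionMatrix(values, list(X.cell_ids), list(X.gene_ids))
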