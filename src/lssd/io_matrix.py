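"""Reading and writing expression matrices, label files and graph matrices.

Supported formats: dense delimited text (TSV/CSV, header row + identifier
column, GEO supplementary-matrix style), Matrix Market triplet directories
(10x style: one ``.mtx`` file plus newline-delimited barcode and feature
sidecar files), and two-column label TSVs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

# Matrices with more than this fraction of zeros are held sparse internally.
SPARSE_ZERO_FRACTION = 0.5

_ORIENTATIONS = ("cells_as_rows", "genes_as_rows")


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """A cells x genes numeric matrix with cell and gene identifiers.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are
    always cells. Identifiers must be unique along each axis.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"identifier lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def validate_counts(self) -> None:
        """Raise if the matrix contains negative entries (not count data)."""
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("count matrix has negative entries")


@dataclass
class LabelVector:
    """Integer cluster/group identities for a set of cells."""

    labels: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")

    def __len__(self) -> int:
        return self.labels.size


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_dense(path: Path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    _check_unique(df.index, "row")
    _check_unique(df.columns, "column")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        # locate the first offending cell for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric value {df.iloc[i, j]!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
        raise
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def _find_sidecar(directory: Path, stems: tuple[str, ...]) -> Path | None:
    for entry in sorted(directory.iterdir()):
        if entry.suffix in (".tsv", ".txt") and any(s in entry.stem for s in stems):
            return entry
    return None


def _read_mtx_dir(directory: Path) -> ExpressionMatrix:
    mtx_files = sorted(directory.glob("*.mtx"))
    if not mtx_files:
        raise FileNotFoundError(f"no .mtx file in {directory}")
    barcodes_f = _find_sidecar(directory, ("barcode", "cell"))
    features_f = _find_sidecar(directory, ("feature", "gene"))
    if barcodes_f is None or features_f is None:
        raise FileNotFoundError(
            f"{directory} must contain barcode and feature sidecar files"
        )
    barcodes = [ln.split("\t")[0] for ln in barcodes_f.read_text().splitlines() if ln]
    features = [ln.split("\t")[0] for ln in features_f.read_text().splitlines() if ln]
    mat = sp.csr_matrix(mmread(mtx_files[0]))
    # 10x convention stores features as rows; accept either orientation and
    # disambiguate from the sidecar lengths.
    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T.tocsr()
    elif mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (features, barcodes)="
            f"({len(features)}, {len(barcodes)}) nor its transpose"
        )
    return ExpressionMatrix(_maybe_sparsify(mat), barcodes, features)


def _maybe_sparsify(values):
    if sp.issparse(values):
        nnz_frac = values.nnz / (values.shape[0] * values.shape[1])
        if 1.0 - nnz_frac > SPARSE_ZERO_FRACTION:
            return values.tocsr()
        return np.asarray(values.todense(), dtype=float)
    values = np.asarray(values, dtype=float)
    if np.count_nonzero(values == 0) / values.size > SPARSE_ZERO_FRACTION:
        return sp.csr_matrix(values)
    return values


def read_expression(path, orientation: str = "cells_as_rows") -> ExpressionMatrix:
    """Read an expression matrix from a dense file or an MTX triplet directory.

    The returned matrix is always oriented cells x genes; ``orientation``
    states how the *input* dense file is laid out. For MTX directories the
    axes are identified by the barcode/feature sidecar lengths.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_mtx_dir(path)
    df = _read_dense(path)
    if orientation == "genes_as_rows":
        df = df.T
    return ExpressionMatrix(
        _maybe_sparsify(df.to_numpy()), list(df.index), list(df.columns)
    )


def write_expression(X: ExpressionMatrix, path, orientation: str = "cells_as_rows") -> None:
    """Write a dense delimited matrix (delimiter from the file extension)."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    path = Path(path)
    df = pd.DataFrame(X.to_dense(), index=X.cell_ids, columns=X.gene_ids)
    if orientation == "genes_as_rows":
        df = df.T
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_mtx_dir(X: ExpressionMatrix, directory) -> None:
    """Write a 10x-style triplet directory (matrix.mtx, barcodes.tsv, features.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = X.values if sp.issparse(X.values) else sp.csr_matrix(X.values)
    mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(mat.T))  # features x barcodes
    (directory / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")
    (directory / "features.tsv").write_text("\n".join(X.gene_ids) + "\n")


def write_labels(labels, cell_ids, path) -> None:
    """Write a two-column (cell_id, cluster) TSV in input cell order."""
    labels = np.asarray(getattr(labels, "labels", labels))
    if labels.size == 0:
        raise ValueError("refusing to write an empty label vector")
    if labels.size != len(cell_ids):
        raise ValueError(
            f"labels length {labels.size} does not match {len(cell_ids)} cell ids"
        )
    pd.DataFrame({"cell_id": list(cell_ids), "cluster": labels.astype(int)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> tuple[LabelVector, list[str]]:
    """Read a label TSV; returns the labels and the cell ids, in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path} is not a two-column label file")
    return LabelVector(df.iloc[:, 1].to_numpy(dtype=int)), list(df.iloc[:, 0])


def write_graph(matrix, cell_ids, path, format: str = "dense_tsv") -> None:
    """Write a square cell-by-cell graph matrix, as-is (no symmetrization)."""
    matrix = np.asarray(matrix) if not sp.issparse(matrix) else matrix
    n, m = matrix.shape
    if n != m:
        raise ValueError(f"graph matrix must be square, got {matrix.shape}")
    if len(cell_ids) != n:
        raise ValueError("cell_ids length does not match matrix size")
    if format == "dense_tsv":
        dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else matrix
        pd.DataFrame(dense, index=cell_ids, columns=cell_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )
    elif format == "mtx":
        mmwrite(str(path), sp.coo_matrix(matrix))
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str = "dense_tsv"):
    """Read a graph matrix written by :func:`write_graph`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df.to_numpy(dtype=float), list(df.index)
    if format == "mtx":
        mat = sp.coo_matrix(mmread(path))
        return mat, None
    raise ValueError(f"unknown graph format {format!r}")
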