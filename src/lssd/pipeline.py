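"""End-to-end orchestration: read -> preprocess -> affinity -> diffuse -> cluster.

`cluster_matrix` is the library entry point operating on an in-memory
matrix; `run_pipeline` wraps it with file I/O, a JSON run manifest and the
clean-up contract used by the command line interface.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .affinity import DEFAULT_K_SCALE, build_affinity
from .clusternum import DEFAULT_C_MAX, DEFAULT_C_MIN, estimate_C
from .clustering import ClusterSolution, spectral_cluster
from .diffusion import DEFAULT_STEPS, DEFAULT_TAU, build_transition, default_knn, self_diffuse, symmetrize
from .io_matrix import ExpressionMatrix, read_expression, write_graph, write_labels
from .preprocess import log1p_transform, select_hvg_vmr


@dataclass
class RunConfig:
    """All user-facing parameters of a pipeline run."""

    input_path: str
    out_dir: str
    orientation: str = "cells_as_rows"
    k_scale: int = DEFAULT_K_SCALE
    knn: int | None = None
    tau: float = DEFAULT_TAU
    steps: int = DEFAULT_STEPS
    n_clusters: int | None = None
    cmin: int = DEFAULT_C_MIN
    cmax: int = DEFAULT_C_MAX
    hvg: int | None = None
    log1p: bool = False
    seed: int = 0
    write_graph: bool = False
    write_curve: bool = False

    def validate(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.n_clusters is None and not 2 <= self.cmin < self.cmax:
            raise ValueError("need 2 <= cmin < cmax when n_clusters is not given")


def diffuse_matrix(
    X,
    k_scale: int = DEFAULT_K_SCALE,
    knn: int | None = None,
    tau: float = DEFAULT_TAU,
    steps: int = DEFAULT_STEPS,
) -> np.ndarray:
    """Affinity construction plus self-diffusion; returns the symmetrized S_t."""
    W = build_affinity(X, k_scale)
    n = W.n_cells
    P = build_transition(W, knn if knn is not None else default_knn(n))
    S = self_diffuse(W, P, t=steps, tau=tau)
    return symmetrize(S)


def cluster_matrix(
    X,
    n_clusters: int | None = None,
    cmin: int = DEFAULT_C_MIN,
    cmax: int = DEFAULT_C_MAX,
    k_scale: int = DEFAULT_K_SCALE,
    knn: int | None = None,
    tau: float = DEFAULT_TAU,
    steps: int = DEFAULT_STEPS,
    hvg: int | None = None,
    log1p: bool = False,
    seed: int = 0,
    return_graph: bool = False,
):
    """Full LSSD clustering of an expression matrix (or raw ndarray).

    When ``n_clusters`` is None the cluster count is estimated on the
    diffused graph by separation-cost minimization over [cmin, cmax].
    """
    if not isinstance(X, ExpressionMatrix):
        X = np.asarray(X, dtype=float)
        X = ExpressionMatrix(
            X,
            [f"cell_{i}" for i in range(X.shape[0])],
            [f"gene_{j}" for j in range(X.shape[1])],
        )
    if hvg is not None:
        X = select_hvg_vmr(X, hvg)
    if log1p:
        X = log1p_transform(X)
    S_sym = diffuse_matrix(X, k_scale=k_scale, knn=knn, tau=tau, steps=steps)
    curve = None
    if n_clusters is None:
        curve = estimate_C(S_sym, cmin, cmax)
        n_clusters = curve.chosen_C
    solution = spectral_cluster(S_sym, n_clusters, seed=seed)
    solution.curve = curve
    solution.provenance = {
        "k_scale": k_scale,
        "knn": knn if knn is not None else default_knn(X.n_cells),
        "tau": tau,
        "steps": steps,
        "hvg": hvg,
        "log1p": log1p,
        "seed": seed,
    }
    if return_graph:
        return solution, S_sym, X
    return solution


def run_pipeline(config: RunConfig) -> Path:
    """Run the pipeline from files to an output directory with a manifest.

    On any error, partially written outputs are removed (if this call
    created the directory) and the exception propagates to the caller.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            X = read_expression(config.input_path, config.orientation)
            solution, S_sym, X_used = cluster_matrix(
                X,
                n_clusters=config.n_clusters,
                cmin=config.cmin,
                cmax=config.cmax,
                k_scale=config.k_scale,
                knn=config.knn,
                tau=config.tau,
                steps=config.steps,
                hvg=config.hvg,
                log1p=config.log1p,
                seed=config.seed,
                return_graph=True,
            )
            captured = [str(w.message) for w in wrec]
        write_labels(solution.labels, X_used.cell_ids, out_dir / "labels.tsv")
        if config.write_graph:
            write_graph(S_sym, X_used.cell_ids, out_dir / "diffused_graph.tsv")
        if config.write_curve and solution.curve is not None:
            curve = solution.curve
            with open(out_dir / "separation_cost.tsv", "w") as fh:
                fh.write("C\tJ\n")
                for c, j in zip(curve.candidates, curve.J_values):
                    fh.write(f"{c}\t{j:.10g}\n")
        manifest = {
            "lssd_version": __version__,
            "config": asdict(config),
            "n_cells": X_used.n_cells,
            "n_genes": X_used.n_genes,
            "chosen_C": int(solution.C),
            "warnings": captured,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return out_dir
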