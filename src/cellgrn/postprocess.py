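"""Partial correlations and network-dynamics summaries.

Precision entries are not comparable across gene pairs; the partial
correlation G(m,n) = −Θ(m,n)/√(Θ(m,m)Θ(n,n)) normalizes them to [−1, 1]
and is the edge weight used everywhere downstream.  The dynamics summaries
quantify rewiring across cells: per-gene total incident weight (mean =
overall regulatory activity, variance = rewiring activity), per-edge
across-cell variance, and thresholded target counts for chosen regulators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GRNTensor

__all__ = [
    "DynamicsSummary",
    "partial_correlation",
    "partial_correlation_tensor",
    "summarize_dynamics",
    "rank_genes_and_edges",
    "write_summary_tables",
]


@dataclass
class DynamicsSummary:
    gene_total_weight: np.ndarray   # n_cells × g: Σ_{n≠m} |G_i(m,n)|
    gene_mean: np.ndarray           # length g, across cells
    gene_var: np.ndarray            # length g, population variance
    edge_var: np.ndarray            # g × g, across-cell variance per edge
    target_counts: np.ndarray       # n_cells × n_regulators
    gene_names: list[str]
    cell_ids: list[str]
    regulators: list[str]
    threshold: float


def partial_correlation(theta: np.ndarray) -> np.ndarray:
    """G(m,n) = −Θ(m,n)/√(Θ(m,m)·Θ(n,n)); diagonal reported as 0
    (self-partial-correlation is not an edge)."""
    theta = np.asarray(theta, dtype=float)
    if np.abs(theta - theta.T).max() > 1e-8:
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(theta)
    if (d <= 0).any():
        raise ValueError("precision diagonal must be strictly positive")
    G = -theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(G, 0.0)
    return G


def partial_correlation_tensor(tensor: GRNTensor) -> GRNTensor:
    """Convert a precision tensor to a partial-correlation tensor."""
    if tensor.kind != "precision":
        raise ValueError("expected a precision tensor")
    nets = np.stack([partial_correlation(t) for t in tensor.networks])
    # clip float fuzz just past ±1 so the tensor invariant holds exactly
    nets = np.clip(nets, -1.0, 1.0)
    return GRNTensor(networks=nets, gene_names=list(tensor.gene_names),
                     cell_ids=list(tensor.cell_ids), kind="partial_correlation")


def summarize_dynamics(
    tensor: GRNTensor,
    regulators: list[str] | None = None,
    threshold: float | None = None,
) -> DynamicsSummary:
    """Across-cell summaries of edge-weight dynamics.

    ``threshold`` defaults to the 90th percentile of |G| over all
    off-diagonal entries of the tensor.  Variances are population variances
    (denominator n: every cell is observed, nothing is sampled).
    """
    if tensor.kind != "partial_correlation":
        raise ValueError("expected a partial-correlation tensor")
    regulators = list(regulators) if regulators else []
    unknown = [r for r in regulators if r not in tensor.gene_names]
    if unknown:
        raise ValueError(f"unknown regulator name(s): {', '.join(unknown)}")
    G = tensor.networks
    n, g, _ = G.shape
    absG = np.abs(G)
    gene_total = absG.sum(axis=2)  # diagonal is 0 by construction
    iu, ju = np.triu_indices(g, k=1)
    if threshold is None:
        threshold = float(np.percentile(absG[:, iu, ju], 90.0)) if iu.size else 0.0
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    reg_idx = [tensor.gene_names.index(r) for r in regulators]
    target_counts = (absG[:, reg_idx, :] > threshold).sum(axis=2)
    return DynamicsSummary(
        gene_total_weight=gene_total,
        gene_mean=gene_total.mean(axis=0),
        gene_var=gene_total.var(axis=0),
        edge_var=G.var(axis=0),
        target_counts=target_counts,
        gene_names=list(tensor.gene_names),
        cell_ids=list(tensor.cell_ids),
        regulators=regulators,
        threshold=float(threshold),
    )


def rank_genes_and_edges(
    summary: DynamicsSummary, top_k: int
) -> tuple[list[str], list[str], list[tuple[str, str]]]:
    """Descending rankings: genes by mean total weight, genes by variance,
    edges by across-cell variance.  Ties broken lexicographically by name."""
    g = len(summary.gene_names)
    n_pairs = g * (g - 1) // 2
    if not 1 <= top_k <= g:
        raise ValueError(f"top_k must be in [1, {g}] for gene rankings")
    names = summary.gene_names

    def _rank(values: np.ndarray) -> list[str]:
        order = sorted(range(g), key=lambda i: (-values[i], names[i]))
        return [names[i] for i in order[:top_k]]

    by_mean = _rank(summary.gene_mean)
    by_var = _rank(summary.gene_var)

    k_edges = min(top_k, n_pairs)
    iu, ju = np.triu_indices(g, k=1)
    pairs = [tuple(sorted((names[i], names[j]))) for i, j in zip(iu, ju)]
    vals = summary.edge_var[iu, ju]
    order = sorted(range(len(pairs)), key=lambda p: (-vals[p], pairs[p]))
    top_edges = [pairs[p] for p in order[:k_edges]]
    return by_mean, by_var, top_edges


def write_summary_tables(summary: DynamicsSummary, out_prefix: str | Path) -> list[Path]:
    """Write gene- and edge-level summary TSVs."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    genes_path = out_prefix.parent / (out_prefix.name + "_genes.tsv")
    pd.DataFrame({
        "gene": summary.gene_names,
        "mean_total_weight": summary.gene_mean,
        "var_total_weight": summary.gene_var,
    }).to_csv(genes_path, sep="\t", index=False)
    g = len(summary.gene_names)
    iu, ju = np.triu_indices(g, k=1)
    names = np.array(summary.gene_names)
    a, b = names[iu].copy(), names[ju].copy()
    flip = a > b
    a[flip], b[flip] = b[flip], a[flip]
    edges_path = out_prefix.parent / (out_prefix.name + "_edge_var.tsv")
    pd.DataFrame({
        "gene_a": a, "gene_b": b, "variance": summary.edge_var[iu, ju],
    }).to_csv(edges_path, sep="\t", index=False)
    return [genes_path, edges_path]
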