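"""Cell-specific prior networks from chromatin accessibility or TF lists.

A prior adjacency G_prior marks gene pairs that are allowed to interact;
its elementwise complement M = 1 − G_prior is the mask whose entries are
ridge-penalized during inference, suppressing edges the prior rules out.

ATAC mode routes every candidate interaction through an accessible region:
a TF f is linked to a region by a motif hit, a target gene t by the region
falling in the strand-aware upstream window of t's TSS, and the (f, t) edge
exists in a cell iff some region accessible in that cell links both.
TF mode is population-level: only target–target pairs are forbidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AccessibilityInputs

logger = logging.getLogger(__name__)

__all__ = ["CellPriorGraph", "prior_from_atac", "prior_from_tf_list", "prior_none"]


@dataclass
class CellPriorGraph:
    """Per-cell binary prior adjacencies and the derived penalty masks."""

    G_prior: np.ndarray  # n_cells × g × g, binary, symmetric, unit diagonal
    mode: str = "none"   # {"atac", "tf", "none"}

    def __post_init__(self) -> None:
        self.G_prior = np.asarray(self.G_prior)
        if self.G_prior.ndim != 3 or self.G_prior.shape[1] != self.G_prior.shape[2]:
            raise ValueError("G_prior must be n_cells × g × g")
        if not np.all(np.isin(np.unique(self.G_prior), (0, 1))):
            raise ValueError("G_prior entries must be 0/1")
        self.G_prior = self.G_prior.astype(np.uint8)
        if (self.G_prior != self.G_prior.transpose(0, 2, 1)).any():
            raise ValueError("G_prior slices must be symmetric")
        diag = self.G_prior[:, np.arange(self.G_prior.shape[1]),
                            np.arange(self.G_prior.shape[1])]
        if not (diag == 1).all():
            raise ValueError("G_prior diagonals must be 1 (self-edges never masked)")
        if self.mode not in ("atac", "tf", "none"):
            raise ValueError("mode must be one of atac/tf/none")

    @property
    def M(self) -> np.ndarray:
        """Penalty masks, the elementwise complement of the prior."""
        return (1 - self.G_prior).astype(np.uint8)

    @property
    def n_cells(self) -> int:
        return self.G_prior.shape[0]

    @property
    def n_genes(self) -> int:
        return self.G_prior.shape[1]


def _window_links(acc: AccessibilityInputs, genes: list[str], window_bp: int) -> np.ndarray:
    """region × gene binary matrix: region overlaps the strand-aware upstream
    window of the gene's TSS.  Windows: [tss−w, tss] for + strand,
    [tss, tss+w] for − strand; overlap is any-base on half-open intervals."""
    n_regions = acc.n_regions
    g = len(genes)
    links = np.zeros((n_regions, g), dtype=bool)
    gene_pos = {name: idx for idx, name in enumerate(genes)}
    rc = acc.region_coords
    r_chrom = rc["chrom"].to_numpy()
    r_start = rc["start"].to_numpy()
    r_end = rc["end"].to_numpy()
    for _, row in acc.tss_table.iterrows():
        gi = gene_pos.get(str(row["gene"]))
        if gi is None:
            continue
        tss = int(row["tss"])
        if str(row["strand"]) == "-":
            lo, hi = tss, tss + window_bp + 1
        else:
            lo, hi = tss - window_bp, tss + 1
        hit = (r_chrom == row["chrom"]) & (r_start < hi) & (lo < r_end)
        links[hit, gi] = True
    return links


def prior_from_atac(
    acc: AccessibilityInputs,
    expr_genes: list[str],
    window_bp: int = 50_000,
) -> CellPriorGraph:
    """Cell-specific prior from accessibility: a TF–gene edge exists in a
    cell iff some region accessible in that cell both carries the TF's motif
    and lies within ``window_bp`` upstream of the gene's TSS.

    Target–target pairs (neither gene motif-linked to a shared region) are
    never created; genes without any link keep only their diagonal entry.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if acc.tss_table is None or len(acc.tss_table) == 0:
        raise ValueError("ATAC-mode prior construction requires a TSS table")
    g = len(expr_genes)
    gene_pos = {name: idx for idx, name in enumerate(expr_genes)}

    # region -> target links by genomic window
    target_links = _window_links(acc, expr_genes, window_bp)
    # region -> TF links by motif hits
    tf_links = np.zeros((acc.n_regions, g), dtype=bool)
    n_dropped = 0
    for region_idx, tf_name in acc.motif_hits:
        gi = gene_pos.get(tf_name)
        if gi is None:
            n_dropped += 1
            continue
        if not 0 <= region_idx < acc.n_regions:
            raise ValueError(f"motif hit references region {region_idx} out of range")
        tf_links[region_idx, gi] = True
    if n_dropped:
        logger.warning("ignored %d motif hit(s) with TFs absent from gene list", n_dropped)

    n = acc.n_cells
    G = np.zeros((n, g, g), dtype=np.uint8)
    for i in range(n):
        active = acc.region_matrix[i].astype(bool)
        if active.any():
            # (f, t) allowed iff an active region links TF f and target t
            adj = tf_links[active].T @ target_links[active]
            adj = adj | adj.T
            G[i][adj] = 1
    idx = np.arange(g)
    G[:, idx, idx] = 1
    return CellPriorGraph(G_prior=G, mode="atac")


def prior_from_tf_list(tf_names: list[str], expr_genes: list[str]) -> CellPriorGraph:
    """Population-level prior from TF knowledge: only target–target pairs are
    forbidden (TF–TF and TF–target interactions remain allowed).

    Returns a single-cell slice; broadcast to all cells with
    :func:`broadcast_prior` or by indexing (the solver accepts either).
    """
    known = set(expr_genes)
    kept = [t for t in tf_names if t in known]
    dropped = [t for t in tf_names if t not in known]
    if dropped:
        logger.warning("dropped %d TF name(s) absent from gene list: %s",
                       len(dropped), ", ".join(sorted(dropped)))
    if not kept:
        raise ValueError("TF list is empty (or disjoint from gene names); "
                         "the prior would forbid every interaction")
    g = len(expr_genes)
    is_tf = np.zeros(g, dtype=bool)
    for t in kept:
        is_tf[expr_genes.index(t)] = True
    adj = np.ones((g, g), dtype=np.uint8)
    non_tf = ~is_tf
    adj[np.ix_(non_tf, non_tf)] = 0
    np.fill_diagonal(adj, 1)
    return CellPriorGraph(G_prior=adj[None, :, :], mode="tf")


def prior_none(n_cells: int, n_genes: int) -> CellPriorGraph:
    """All-ones prior: the mask is all-zero and the β-term is inert."""
    G = np.ones((n_cells, n_genes, n_genes), dtype=np.uint8)
    return CellPriorGraph(G_prior=G, mode="none")
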