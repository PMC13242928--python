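"""Kernel weights between cells from expression or spatial geometry.

The per-cell objective borrows data from neighboring cells with a Gaussian
kernel on geodesic distances, K_ij = exp(-D_ij^2 / (2 sigma^2)).  Distances
are shortest paths on a symmetric k-nearest-neighbor graph: in expression
mode the graph is built in PCA space (a manifold-distance approximation),
in spatial mode directly on physical coordinates.  Both modes share every
step after the Euclidean distance matrix is built
(:func:`kernel_from_distances`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import (
    connected_components,
    csgraph_from_dense,
    shortest_path,
)
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, SpatialCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "KernelWeights",
    "NeighborSets",
    "expression_kernel",
    "spatial_kernel",
    "kernel_from_distances",
    "neighbor_sets",
]


@dataclass
class KernelWeights:
    """Pairwise kernel weights K, geodesic distances D and their parameters."""

    K: np.ndarray
    geodesic_D: np.ndarray
    bandwidth: float
    knn_k: int

    @property
    def n_cells(self) -> int:
        return self.K.shape[0]


@dataclass
class NeighborSets:
    """Index sets: ``objective_neighbors[i]`` weights the likelihood terms of
    cell i's solve; ``covariance_neighbors[j]`` pools cells for cell j's
    rank-correlation covariance estimate (needs at least 2 cells)."""

    objective_neighbors: list[np.ndarray]
    covariance_neighbors: list[np.ndarray]

    @property
    def n_cells(self) -> int:
        return len(self.objective_neighbors)


def _knn_geodesic(euclid: np.ndarray, k: int) -> np.ndarray:
    """All-pairs shortest-path distances on the symmetric kNN graph of a
    Euclidean distance matrix.  Disconnected components are bridged by the
    single shortest inter-component Euclidean edge (logged)."""
    n = euclid.shape[0]
    # k nearest neighbors excluding self; union (edge kept if either endpoint
    # lists the other) gives a symmetric graph.  Adjacency is tracked
    # explicitly so zero-length edges (coincident cells) survive.
    order = np.argsort(euclid + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    adj[rows, cols] = True
    adj |= adj.T

    def _components(adjacency: np.ndarray):
        return connected_components(csr_matrix(adjacency), directed=False)

    n_comp, labels = _components(adj)
    if n_comp > 1:
        logger.info("kNN graph has %d components; bridging minimally", n_comp)
        while n_comp > 1:
            # shortest Euclidean edge between any two distinct components
            diff = labels[:, None] != labels[None, :]
            masked = np.where(diff, euclid, np.inf)
            i, j = np.unravel_index(np.argmin(masked), masked.shape)
            adj[i, j] = adj[j, i] = True
            logger.info("bridged components via cells %d-%d (d=%.4g)",
                        i, j, euclid[i, j])
            n_comp, labels = _components(adj)

    dense = np.where(adj, euclid, np.inf)
    np.fill_diagonal(dense, 0.0)
    graph = csgraph_from_dense(dense, null_value=np.inf)
    D = shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def kernel_from_distances(
    euclid: np.ndarray, k: int, sigma: float | None = None
) -> KernelWeights:
    """Shared tail of both kernel modes: kNN graph -> geodesic D -> Gaussian K.

    ``sigma=None`` uses the heuristic median(off-diagonal D)/2.
    """
    euclid = np.asarray(euclid, dtype=float)
    n = euclid.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells n={n}")
    D = _knn_geodesic(euclid, k)
    if sigma is None:
        iu = np.triu_indices(n, k=1)
        sigma = float(np.median(D[iu])) / 2.0
        if sigma <= 0:  # all cells coincide
            sigma = 1.0
        logger.info("bandwidth heuristic: sigma = median(D)/2 = %.4g", sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    K = np.exp(-(D**2) / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return KernelWeights(K=K, geodesic_D=D, bandwidth=float(sigma), knn_k=int(k))


def expression_kernel(
    expr: ExpressionMatrix,
    n_pcs: int = 20,
    k: int = 5,
    sigma: float | None = None,
) -> KernelWeights:
    """Kernel weights from expression: PCA -> Euclidean -> kNN geodesic -> K.

    ``n_pcs`` is capped at min(n_cells, n_genes) − 1.
    """
    if n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    n, g = expr.values.shape
    n_pcs = min(n_pcs, min(n, g) - 1)
    if n_pcs < 1:
        raise ValueError("need at least 2 cells and 2 genes for PCA")
    X = expr.values - expr.values.mean(axis=0, keepdims=True)
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=0).fit_transform(X)
    euclid = squareform(pdist(pcs))
    return kernel_from_distances(euclid, k=k, sigma=sigma)


def spatial_kernel(
    coords: SpatialCoordinates, k: int = 5, sigma: float | None = None
) -> KernelWeights:
    """Kernel weights from physical coordinates; identical pipeline to
    :func:`expression_kernel` with the PCA step skipped."""
    euclid = squareform(pdist(coords.coords))
    return kernel_from_distances(euclid, k=k, sigma=sigma)


def neighbor_sets(
    kernel: KernelWeights, n_objective: int, n_covariance: int
) -> NeighborSets:
    """The two neighborhood systems, each the cells geodesically closest to
    the anchor (self always included; ties broken by ascending cell index)."""
    n = kernel.n_cells
    if not 1 <= n_objective <= n:
        raise ValueError(f"n_objective must be in [1, {n}]")
    if not 2 <= n_covariance <= n:
        raise ValueError(f"n_covariance must be in [2, {n}] (pairs are needed)")
    obj: list[np.ndarray] = []
    cov: list[np.ndarray] = []
    for i in range(n):
        key = kernel.geodesic_D[i].copy()
        key[i] = -1.0  # self strictly first even under distance ties
        order = np.argsort(key, kind="stable")
        obj.append(np.sort(order[:n_objective]))
        cov.append(np.sort(order[:n_covariance]))
    return NeighborSets(objective_neighbors=obj, covariance_neighbors=cov)
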