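"""Nonparametric per-cell covariance via kernel- and zero-weighted Kendall's τ.

Single-cell expression is far from Gaussian, so the latent covariance of
the copula model is estimated rank-based: for each cell j, Kendall's τ is
computed over ordered pairs of cells in j's covariance neighborhood, with
each pair weighted by the kernel similarity of the two cells and annihilated
whenever either cell has a zero (dropout) in either gene.  The sine
transform sin(π/2·τ) then recovers the latent Pearson correlation
(Greiner's identity), and an eigenvalue floor makes each estimate positive
definite.

The denominator of τ is the unweighted ordered-pair count |Nj|(|Nj|−1);
weights only shrink the numerator, biasing τ toward 0 in zero-rich or
low-weight neighborhoods.  ``normalize_by_weight=True`` switches to a
Σw denominator (off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix
from .kernel import KernelWeights, NeighborSets

logger = logging.getLogger(__name__)

__all__ = [
    "CellCovariance",
    "weighted_kendall_tau",
    "tau_to_covariance",
    "project_positive_definite",
    "all_cell_covariances",
]


@dataclass
class CellCovariance:
    """Per-cell covariance estimates Σ̂_j (PD after projection)."""

    Sigma: np.ndarray           # n_cells × g × g
    epsilon: float = 1e-3       # eigenvalue floor used in the PD projection
    tau: np.ndarray | None = None  # optional retained τ tensor

    @property
    def n_cells(self) -> int:
        return self.Sigma.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Sigma.shape[1]


def weighted_kendall_tau(
    expr: ExpressionMatrix,
    kernel: KernelWeights,
    neighbors: NeighborSets,
    cell_j: int,
    normalize_by_weight: bool = False,
) -> np.ndarray:
    """Neighborhood-weighted Kendall's τ matrix for one cell.

    τ_j(m,n) = Σ_{k≠k' ∈ Nj} w_kk'^{mn} · sign((X_km−X_k'm)(X_kn−X_k'n))
               / (|Nj|·(|Nj|−1)),
    with w_kk'^{mn} = b_km b_k'm b_kn b_k'n K_kk' and b_km = [X_km ≠ 0].
    Tied nonzero values contribute sign 0.  The diagonal is computed by the
    same formula but is overwritten downstream (Σ̂ diagonal is pinned to 1).
    """
    nj = neighbors.covariance_neighbors[cell_j]
    N = len(nj)
    if N < 2:
        raise ValueError("covariance neighborhood must contain at least 2 cells")
    X = expr.values[nj]               # N × g
    B = (X != 0)
    ia, ib = np.triu_indices(N, k=1)  # unordered pairs; ordered sum = 2×
    # sign(X_a - X_b) per gene, annihilated when either value is zero
    U = np.sign(X[ia] - X[ib]) * (B[ia] & B[ib])
    w = kernel.K[nj[ia], nj[ib]]
    tau = 2.0 * (U * w[:, None]).T @ U
    if normalize_by_weight:
        # per-entry Σ over ordered pairs of w_kk'^mn
        P = (B[ia] & B[ib]).astype(float)
        denom = 2.0 * (P * w[:, None]).T @ P
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(denom > 0, tau / denom, 0.0)
    else:
        tau /= N * (N - 1)
    return tau


def tau_to_covariance(tau: np.ndarray) -> np.ndarray:
    """Sine transform sin(π/2·τ) off-diagonal; exact 1 on the diagonal."""
    tau = np.asarray(tau, dtype=float)
    if np.abs(tau).max() > 1 + 1e-12:
        raise ValueError("|tau| exceeds 1 beyond numerical tolerance")
    S = np.sin(np.pi / 2.0 * np.clip(tau, -1.0, 1.0))
    np.fill_diagonal(S, 1.0)
    return S


def project_positive_definite(S: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Replace non-positive eigenvalues with ``epsilon``; already-PD input is
    returned unchanged (up to a copy)."""
    S = np.asarray(S, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("input matrix is not symmetric")
    w, V = np.linalg.eigh(S)
    if w[0] > 0:
        return S.copy()
    w = np.where(w <= 0, epsilon, w)
    out = (V * w) @ V.T
    return (out + out.T) / 2.0


def all_cell_covariances(
    expr: ExpressionMatrix,
    kernel: KernelWeights,
    neighbors: NeighborSets,
    epsilon: float = 1e-3,
    store_tau: bool = False,
    normalize_by_weight: bool = False,
) -> CellCovariance:
    """τ -> sine transform -> PD projection for every cell.

    Cells are independent, so the result does not depend on evaluation order.
    """
    n, g = expr.values.shape
    Sigma = np.empty((n, g, g))
    taus = np.empty((n, g, g)) if store_tau else None
    for j in range(n):
        tau = weighted_kendall_tau(expr, kernel, neighbors, j,
                                   normalize_by_weight=normalize_by_weight)
        if store_tau:
            taus[j] = tau
        Sigma[j] = project_positive_definite(tau_to_covariance(tau), epsilon)
        if n >= 50 and (j + 1) % max(1, n // 10) == 0:
            logger.info("covariance: %d/%d cells", j + 1, n)
    return CellCovariance(Sigma=Sigma, epsilon=epsilon, tau=taus)
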