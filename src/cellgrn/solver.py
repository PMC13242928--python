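"""Per-cell penalized Gaussian-copula likelihood solves via ADMM.

For cell i the (normalized) problem is

    minimize_{Θ ≻ 0}  −log det Θ + tr(S̄_i Θ) + λ‖Θ‖₁,off + β‖M_i ⊙ Θ‖²_F

where S̄_i is the kernel-weighted average of neighborhood covariance
estimates and M_i the binary mask of prior-forbidden edges (zero diagonal).
The ℓ1 penalty is applied to off-diagonal entries only — the standard
graphical-lasso convention, which keeps the precision diagonal unbiased.

ADMM splits Θ (likelihood) from Z (penalties) under the consensus
constraint Θ = Z.  The Θ-update has a closed form via eigendecomposition
that keeps every iterate strictly positive definite; the Z-update is the
exact prox of the combined ℓ1 + masked-ridge penalty (soft-threshold, then
shrink masked entries by ρ/(ρ+2β)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .covariance import CellCovariance
from .io import ExpressionMatrix, GRNTensor
from .kernel import KernelWeights, NeighborSets
from .prior import CellPriorGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "SolveResult",
    "assemble_cell_data",
    "admm_solve",
    "infer_all_cells",
]


@dataclass
class SolverConfig:
    """Hyperparameters of the per-cell solve.

    ``lam``/``beta`` are the sparsity and mask weights.  With
    ``scale_penalties=True`` (default) they apply to the normalized
    likelihood −log det Θ + tr(S̄Θ), so their meaning is comparable across
    cells regardless of neighborhood mass; ``False`` restores the raw
    objective scaling where the effective penalties are 2λ/(|Ni|·W_i).
    """

    lam: float = 0.05
    beta: float = 0.0
    rho: float = 1.0
    max_iter: int = 1000
    tol_primal: float = 1e-5
    tol_dual: float = 1e-5
    init: str = "identity"          # {"identity", "inverse_sigma"}
    scale_penalties: bool = True
    adapt_rho: bool = False         # residual balancing (factor 2, bounded)

    def __post_init__(self) -> None:
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.init not in ("identity", "inverse_sigma"):
            raise ValueError("init must be 'identity' or 'inverse_sigma'")


@dataclass
class SolveResult:
    """Outcome of one per-cell ADMM solve."""

    theta: np.ndarray               # symmetrized (Θ+Z)/2 — strictly PD estimate
    z: np.ndarray                   # soft-thresholded iterate (exact zeros)
    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool
    min_eig_trace: list[float] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)


def assemble_cell_data(
    kernel: KernelWeights,
    neighbors: NeighborSets,
    cov: CellCovariance,
    cell_i: int,
) -> tuple[np.ndarray, float]:
    """Kernel-weighted average covariance S̄_i and total weight W_i over the
    objective neighborhood of cell i.

    The cell's objective is proportional to −log det Θ + tr(S̄_i Θ) plus
    penalties rescaled by 2/(|Ni|·W_i) — same argmin as the raw weighted sum.
    """
    ni = neighbors.objective_neighbors[cell_i]
    w = kernel.K[cell_i, ni]
    Wi = float(w.sum())
    Sbar = np.tensordot(w, cov.Sigma[ni], axes=(0, 0)) / Wi
    return (Sbar + Sbar.T) / 2.0, Wi


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def admm_solve(
    S: np.ndarray,
    mask: np.ndarray | None,
    config: SolverConfig,
    penalty_scale: float = 1.0,
    track: bool = False,
) -> SolveResult:
    """Solve the penalized likelihood problem for one data matrix S.

    ``penalty_scale`` multiplies ``config.lam``/``config.beta`` (used by
    :func:`infer_all_cells` for raw objective scaling).  With ``track=True``
    the smallest eigenvalue of every Θ-iterate and the objective value are
    recorded.
    """
    S = np.asarray(S, dtype=float)
    g = S.shape[0]
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("S must be symmetric")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != S.shape:
            raise ValueError("mask shape must match S")
        if np.diag(mask).any():
            raise ValueError("mask diagonal must be zero (never penalize Θ's diagonal)")
    lam = config.lam * penalty_scale
    beta = config.beta * penalty_scale
    rho = config.rho

    if config.init == "inverse_sigma":
        w0, V0 = np.linalg.eigh(S)
        w0 = np.maximum(w0, 1e-6)
        Z = (V0 / w0) @ V0.T
    else:
        Z = np.eye(g)
    U = np.zeros((g, g))
    Theta = Z.copy()
    off_mask = ~np.eye(g, dtype=bool)

    min_eig_trace: list[float] = []
    objective_trace: list[float] = []
    converged = False
    r_primal = r_dual = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        # Θ-update: closed form keeping Θ ≻ 0
        A = rho * (Z - U) - S
        w, Q = np.linalg.eigh(A)
        theta_eig = (w + np.sqrt(w**2 + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_eig) @ Q.T
        Theta = (Theta + Theta.T) / 2.0
        if track:
            min_eig_trace.append(float(theta_eig.min()))
            sign, ld = np.linalg.slogdet(Theta)
            obj = -ld + float(np.sum(S * Theta)) + lam * np.abs(Theta[off_mask]).sum()
            if mask is not None and beta > 0:
                obj += beta * float(np.sum((Theta * mask) ** 2))
            objective_trace.append(obj)

        # Z-update: prox of λ‖·‖₁(off-diagonal) + β‖M⊙·‖²_F
        V = Theta + U
        Z_prev = Z
        Z = _soft(V, lam / rho)
        np.fill_diagonal(Z, np.diag(V))
        if mask is not None and beta > 0:
            Z = np.where(mask, Z * (rho / (rho + 2.0 * beta)), Z)

        U = U + Theta - Z

        r_primal = float(np.linalg.norm(Theta - Z))
        r_dual = float(rho * np.linalg.norm(Z - Z_prev))
        if r_primal <= config.tol_primal * g and r_dual <= config.tol_dual * g:
            converged = True
            break
        if not np.all(np.isfinite(Theta)):
            raise FloatingPointError(
                f"non-finite ADMM iterate at iteration {it} "
                f"(rho={rho}, lam={lam}, beta={beta})"
            )
        if config.adapt_rho and it % 10 == 0:
            if r_primal > 10 * r_dual and rho < 1e3:
                rho *= 2.0
                U /= 2.0
            elif r_dual > 10 * r_primal and rho > 1e-3:
                rho /= 2.0
                U *= 2.0

    theta_hat = (Theta + Z) / 2.0
    theta_hat = (theta_hat + theta_hat.T) / 2.0
    if np.linalg.eigvalsh(theta_hat)[0] <= 0:
        theta_hat = Theta  # Θ-iterate is PD by construction
    return SolveResult(
        theta=theta_hat,
        z=(Z + Z.T) / 2.0,
        iterations=it,
        primal_residual=r_primal,
        dual_residual=r_dual,
        converged=converged,
        min_eig_trace=min_eig_trace,
        objective_trace=objective_trace,
    )


def infer_all_cells(
    expr: ExpressionMatrix,
    kernel: KernelWeights,
    neighbors: NeighborSets,
    cov: CellCovariance,
    priors: CellPriorGraph | None,
    config: SolverConfig,
    return_results: bool = False,
) -> GRNTensor | tuple[GRNTensor, list[SolveResult]]:
    """Assemble and solve the objective for every cell independently.

    ``priors`` may be None (no mask), a single-slice prior broadcast to all
    cells, or one slice per cell.  Non-converged cells are flagged with a
    warning, never a crash.
    """
    n, g = expr.values.shape
    if priors is not None and priors.n_cells not in (1, n):
        raise ValueError("priors must have 1 slice or one per cell")
    thetas = np.empty((n, g, g))
    results: list[SolveResult] = []
    n_fail = 0
    for i in range(n):
        Sbar, Wi = assemble_cell_data(kernel, neighbors, cov, i)
        if priors is None:
            mask = None
        else:
            Mi = priors.M[0 if priors.n_cells == 1 else i]
            mask = Mi if Mi.any() else None
        scale = 1.0
        if not config.scale_penalties:
            scale = 2.0 / (len(neighbors.objective_neighbors[i]) * Wi)
        res = admm_solve(Sbar, mask, config, penalty_scale=scale)
        if not res.converged:
            n_fail += 1
            logger.warning(
                "cell %s: ADMM not converged after %d iterations "
                "(primal %.2e, dual %.2e)",
                expr.cell_ids[i], res.iterations, res.primal_residual,
                res.dual_residual,
            )
        thetas[i] = res.theta
        if return_results:
            results.append(res)
        if n >= 50 and (i + 1) % max(1, n // 10) == 0:
            logger.info("solver: %d/%d cells", i + 1, n)
    if n_fail:
        logger.warning("%d/%d cells did not reach the convergence tolerance", n_fail, n)
    tensor = GRNTensor(networks=thetas, gene_names=list(expr.gene_names),
                       cell_ids=list(expr.cell_ids), kind="precision")
    if return_results:
        return tensor, results
    return tensor
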