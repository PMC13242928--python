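"""Synthetic benchmarks with known cell-specific network ground truth.

The generator emulates the statistical structure of a single-cell
multi-omics simulation: a sequence of sparse positive-definite precision
matrices that rewire smoothly along a 1-D trajectory (or a smooth 2-D
spatial field), copula-transformed non-Gaussian expression with excess
zeros, and per-cell prior graphs corrupted at a configurable
cross-modality noise rate.

Ground-truth precisions are kept positive definite by strict diagonal
dominance (diagonal = off-diagonal absolute row sum + 0.1), which preserves
the designed edge support exactly.  Expression follows the copula model the
inference assumes: one latent Gaussian draw per cell from its own
precision, pushed through a monotone marginal (log-normal by default), then
independent Bernoulli dropout — the zeros that the τ estimator's zero
indicators exist to handle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .prior import CellPriorGraph

__all__ = [
    "SimulationTruth",
    "simulate_grn_sequence",
    "sample_expression",
    "corrupt_priors",
    "write_simulated_dataset",
]

_SUPPORT_TOL = 1e-12


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset."""

    precisions: np.ndarray          # n × g × g, each strictly PD
    supports: np.ndarray            # n × g × g binary, zero diagonal
    positions: np.ndarray           # length n: pseudotime or smooth field value
    coords: np.ndarray | None       # n × 2 for spatial layout, else None
    layout: str
    gene_names: list[str]
    cell_ids: list[str]
    seed: int
    density: float

    @property
    def n_cells(self) -> int:
        return self.precisions.shape[0]

    @property
    def n_genes(self) -> int:
        return self.precisions.shape[1]

    def prior_support(self) -> np.ndarray:
        """True supports with unit diagonal — the uncorrupted prior graphs."""
        G = self.supports.astype(np.uint8).copy()
        idx = np.arange(self.n_genes)
        G[:, idx, idx] = 1
        return G


def _diagonal_dominant(W: np.ndarray) -> np.ndarray:
    """Off-diagonal weights -> PD precision via diagonal dominance."""
    theta = W.copy()
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 0.1)
    return theta


def simulate_grn_sequence(
    g: int,
    n: int,
    density: float = 0.1,
    n_rewire_events: int = 2,
    layout: str = "trajectory",
    seed: int = 0,
    rewire_fraction: float = 0.3,
    weight_range: tuple[float, float] = (0.2, 1.0),
) -> SimulationTruth:
    """A sequence of sparse PD precision matrices rewiring smoothly.

    A random symmetric support at the given edge density anchors the start;
    at ``n_rewire_events`` evenly spaced anchor points a small random subset
    of edges (``rewire_fraction`` of the edge count, at least 1) is toggled
    on/off, and edge weights are interpolated linearly between anchors.
    ``layout="trajectory"`` places cells on a 1-D pseudotime; ``"spatial2d"``
    scatters cells in the unit square and uses a smooth linear field across
    it as the interpolation coordinate.
    """
    if g < 4:
        raise ValueError("need at least 4 genes")
    if not 0 < density < 0.5:
        raise ValueError("density must be in (0, 0.5)")
    if layout not in ("trajectory", "spatial2d"):
        raise ValueError("layout must be 'trajectory' or 'spatial2d'")
    rng = np.random.default_rng(seed)
    n_pairs = g * (g - 1) // 2
    n_edges = int(round(density * n_pairs))
    if n_edges == 0:
        raise ValueError("density too small: zero edges")
    iu, ju = np.triu_indices(g, k=1)

    def rand_weight(size: int) -> np.ndarray:
        mag = rng.uniform(*weight_range, size=size)
        return mag * rng.choice((-1.0, 1.0), size=size)

    # anchor 0
    w_pairs = np.zeros(n_pairs)
    edge_idx = rng.choice(n_pairs, size=n_edges, replace=False)
    w_pairs[edge_idx] = rand_weight(n_edges)
    anchors = [w_pairs.copy()]
    n_toggle = max(1, int(round(rewire_fraction * n_edges)))
    for _ in range(n_rewire_events):
        w_pairs = w_pairs.copy()
        toggled = rng.choice(n_pairs, size=n_toggle, replace=False)
        for p in toggled:
            if abs(w_pairs[p]) > _SUPPORT_TOL:
                w_pairs[p] = 0.0
            else:
                w_pairs[p] = rand_weight(1)[0]
        anchors.append(w_pairs.copy())
    anchor_mat = np.stack(anchors)  # (E+1) × n_pairs

    if layout == "trajectory":
        positions = np.linspace(0.0, 1.0, n)
        coords = None
    else:
        coords = rng.uniform(0.0, 1.0, size=(n, 2))
        s = coords.sum(axis=1)
        positions = (s - s.min()) / max(s.max() - s.min(), 1e-12)

    E = len(anchors) - 1
    precisions = np.empty((n, g, g))
    supports = np.zeros((n, g, g), dtype=np.uint8)
    anchor_pos = np.linspace(0.0, 1.0, E + 1) if E else np.array([0.0])
    for i, t in enumerate(positions):
        if E == 0:
            wv = anchor_mat[0]
        else:
            wv = np.empty(anchor_mat.shape[1])
            for p in range(anchor_mat.shape[1]):
                wv[p] = np.interp(t, anchor_pos, anchor_mat[:, p])
        W = np.zeros((g, g))
        W[iu, ju] = wv
        W = W + W.T
        precisions[i] = _diagonal_dominant(W)
        sup = (np.abs(W) > _SUPPORT_TOL).astype(np.uint8)
        np.fill_diagonal(sup, 0)
        supports[i] = sup

    return SimulationTruth(
        precisions=precisions,
        supports=supports,
        positions=positions,
        coords=coords,
        layout=layout,
        gene_names=[f"g{m}" for m in range(g)],
        cell_ids=[f"cell_{i}" for i in range(n)],
        seed=int(seed),
        density=float(density),
    )


def sample_expression(
    truth: SimulationTruth,
    dropout_rate: float = 0.2,
    marginal: str = "lognormal",
    seed: int = 0,
) -> ExpressionMatrix:
    """One copula draw per cell from that cell's precision matrix.

    The latent draw z ~ N(0, Θ_i⁻¹) is standardized per gene, mapped through
    the standard-normal CDF and the chosen marginal quantile function
    (``lognormal`` or ``exponential``; ``gaussian`` keeps the latent values,
    for calibration checks only), then thinned by independent Bernoulli
    dropout at ``dropout_rate``.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if marginal not in ("lognormal", "exponential", "gaussian"):
        raise ValueError("marginal must be lognormal/exponential/gaussian")
    rng = np.random.default_rng(seed)
    n, g = truth.n_cells, truth.n_genes
    Z = np.empty((n, g))
    for i in range(n):
        cov = np.linalg.inv(truth.precisions[i])
        L = np.linalg.cholesky(cov)
        z = L @ rng.standard_normal(g)
        Z[i] = z / np.sqrt(np.diag(cov))  # standardized latent values
    if marginal == "gaussian":
        X = Z
    else:
        u = stats.norm.cdf(Z)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        if marginal == "lognormal":
            X = stats.lognorm.ppf(u, s=1.0)
        else:
            X = stats.expon.ppf(u)
    if dropout_rate > 0:
        X = np.where(rng.random((n, g)) < dropout_rate, 0.0, X)
    return ExpressionMatrix(
        values=X,
        gene_names=list(truth.gene_names),
        cell_ids=list(truth.cell_ids),
        check_nonnegative=(marginal != "gaussian"),
    )


def corrupt_priors(
    truth: SimulationTruth, noise_level: float, seed: int = 0
) -> CellPriorGraph:
    """Flip each off-diagonal prior entry independently (and symmetrically)
    with probability ``noise_level``; the diagonal stays 1."""
    if not 0 <= noise_level < 1:
        raise ValueError("noise_level must be in [0, 1)")
    rng = np.random.default_rng(seed)
    G = truth.prior_support().copy()
    n, g, _ = G.shape
    iu, ju = np.triu_indices(g, k=1)
    for i in range(n):
        flips = rng.random(iu.size) < noise_level
        vals = G[i][iu, ju]
        vals[flips] = 1 - vals[flips]
        G[i][iu, ju] = vals
        G[i][ju, iu] = vals
    return CellPriorGraph(G_prior=G, mode="atac")


def write_simulated_dataset(
    truth: SimulationTruth,
    expr: ExpressionMatrix,
    priors: CellPriorGraph | None,
    out_prefix: str | Path,
) -> list[Path]:
    """Write a simulated dataset in the formats the readers accept:
    expression CSV, coordinate CSV (spatial layouts), truth archive and
    prior archive."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    expr_path = out_prefix.parent / (out_prefix.name + "_expression.csv")
    pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_names) \
        .to_csv(expr_path, index_label="cell_id")
    written.append(expr_path)

    if truth.coords is not None:
        coords_path = out_prefix.parent / (out_prefix.name + "_coords.csv")
        pd.DataFrame(truth.coords, index=truth.cell_ids, columns=["x", "y"]) \
            .to_csv(coords_path, index_label="cell_id")
        written.append(coords_path)

    truth_path = out_prefix.parent / (out_prefix.name + "_truth.npz")
    np.savez_compressed(
        truth_path,
        precisions=truth.precisions,
        supports=truth.supports,
        positions=truth.positions,
        coords=truth.coords if truth.coords is not None else np.empty((0, 2)),
        layout=np.array(truth.layout),
        gene_names=np.array(truth.gene_names),
        cell_ids=np.array(truth.cell_ids),
        seed=np.array(truth.seed),
        density=np.array(truth.density),
    )
    written.append(truth_path)

    if priors is not None:
        prior_path = out_prefix.parent / (out_prefix.name + "_priors.npz")
        np.savez_compressed(prior_path, G_prior=priors.G_prior,
                            mode=np.array(priors.mode))
        written.append(prior_path)
    return written


def read_simulation_truth(npz_path: str | Path) -> SimulationTruth:
    """Read a truth archive written by :func:`write_simulated_dataset`."""
    with np.load(npz_path, allow_pickle=False) as d:
        coords = d["coords"]
        return SimulationTruth(
            precisions=d["precisions"],
            supports=d["supports"],
            positions=d["positions"],
            coords=coords if coords.size else None,
            layout=str(d["layout"]),
            gene_names=[str(x) for x in d["gene_names"]],
            cell_ids=[str(x) for x in d["cell_ids"]],
            seed=int(d["seed"]),
            density=float(d["density"]),
        )
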