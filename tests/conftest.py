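import numpy as np
import pytest

from cellgrn import (
    ExpressionMatrix,
    all_cell_covariances,
    expression_kernel,
    neighbor_sets,
    sample_expression,
    simulate_grn_sequence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pd(rng, g, n_samples=None):
    """Random well-conditioned PD matrix (sample covariance of a Gaussian)."""
    n_samples = n_samples or 3 * g
    A = rng.standard_normal((g, n_samples))
    S = A @ A.T / n_samples
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


@pytest.fixture
def small_expr():
    """6 cells × 4 genes with some exact zeros and ties."""
    values = np.array([
        [1.0, 0.0, 2.0, 3.0],
        [2.0, 1.0, 1.0, 0.0],
        [0.5, 2.0, 1.0, 1.5],
        [3.0, 0.5, 0.0, 2.0],
        [1.0, 1.5, 2.5, 0.5],
        [2.5, 3.0, 0.5, 1.0],
    ])
    return ExpressionMatrix(values=values,
                            gene_names=[f"g{i}" for i in range(4)],
                            cell_ids=[f"c{i}" for i in range(6)])


@pytest.fixture(scope="session")
def small_dataset():
    """30-cell simulated trajectory with expression, kernel, neighborhoods
    and covariances — the shared end-to-end fixture."""
    truth = simulate_grn_sequence(g=8, n=30, density=0.15, n_rewire_events=1,
                                  layout="trajectory", seed=7)
    expr = sample_expression(truth, dropout_rate=0.1, seed=8)
    kern = expression_kernel(expr, n_pcs=5, k=3)
    nbrs = neighbor_sets(kern, n_objective=8, n_covariance=8)
    cov = all_cell_covariances(expr, kern, nbrs)
    return {"truth": truth, "expr": expr, "kernel": kern,
            "neighbors": nbrs, "cov": cov}
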