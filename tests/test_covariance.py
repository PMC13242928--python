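import numpy as np
import pytest
from scipy.stats import kendalltau

from cellgrn import (
    ExpressionMatrix,
    all_cell_covariances,
    project_positive_definite,
    tau_to_covariance,
    weighted_kendall_tau,
)
from cellgrn.kernel import KernelWeights, NeighborSets


def uniform_kernel(n):
    return KernelWeights(K=np.ones((n, n)), geodesic_D=np.zeros((n, n)),
                         bandwidth=1.0, knn_k=max(n - 1, 1))


def all_neighbors(n):
    return NeighborSets(objective_neighbors=[np.arange(n)] * n,
                        covariance_neighbors=[np.arange(n)] * n)


def expr_from(values):
    values = np.asarray(values, float)
    n, g = values.shape
    return ExpressionMatrix(values=values,
                            gene_names=[f"g{i}" for i in range(g)],
                            cell_ids=[f"c{i}" for i in range(n)])


def tau_oracle(X, K, neighborhood):
    """Quadruple-loop transcription of the weighted tau formula."""
    g = X.shape[1]
    N = len(neighborhood)
    tau = np.zeros((g, g))
    for m in range(g):
        for n in range(g):
            acc = 0.0
            for k in neighborhood:
                for kp in neighborhood:
                    if k == kp:
                        continue
                    b = (X[k, m] != 0) * (X[kp, m] != 0) * \
                        (X[k, n] != 0) * (X[kp, n] != 0)
                    s = np.sign((X[k, m] - X[kp, m]) * (X[k, n] - X[kp, n]))
                    acc += b * K[k, kp] * s
            tau[m, n] = acc / (N * (N - 1))
    return tau


class TestWeightedKendallTau:
    def test_perfectly_concordant_genes(self):
        X = np.column_stack([np.arange(1, 5), np.arange(2, 6)])
        expr = expr_from(X)
        tau = weighted_kendall_tau(expr, uniform_kernel(4), all_neighbors(4), 0)
        np.testing.assert_allclose(tau[0, 1], 1.0)

    def test_all_zero_gene_annihilates_row(self):
        X = np.array([[1.0, 0.0, 2.0], [2.0, 0.0, 1.0], [3.0, 0.0, 3.0]])
        expr = expr_from(X)
        tau = weighted_kendall_tau(expr, uniform_kernel(3), all_neighbors(3), 0)
        np.testing.assert_array_equal(tau[1, :], 0.0)
        np.testing.assert_array_equal(tau[:, 1], 0.0)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_quadruple_loop_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 9))
        g = int(rng.integers(2, 6))
        X = rng.integers(0, 4, size=(n, g)).astype(float)  # many zeros & ties
        D = np.abs(rng.standard_normal((n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        kern = KernelWeights(K=np.exp(-D), geodesic_D=D, bandwidth=1.0, knn_k=2)
        nj = np.sort(rng.choice(n, size=int(rng.integers(2, n + 1)),
                                replace=False))
        nbrs = NeighborSets(objective_neighbors=[nj] * n,
                            covariance_neighbors=[nj] * n)
        expr = expr_from(X)
        tau = weighted_kendall_tau(expr, kern, nbrs, 0)
        np.testing.assert_allclose(tau, tau_oracle(X, kern.K, nj), atol=1e-12)

    def test_reduces_to_classical_tau(self, rng):
        # no zeros, unit weights: equals scipy's Kendall tau (no ties)
        X = rng.standard_normal((12, 3)) + 10.0
        expr = expr_from(np.abs(X))
        tau = weighted_kendall_tau(expr, uniform_kernel(12), all_neighbors(12), 0)
        for m in range(3):
            for n in range(m + 1, 3):
                ref = kendalltau(expr.values[:, m], expr.values[:, n]).statistic
                np.testing.assert_allclose(tau[m, n], ref, atol=1e-12)

    def test_requires_two_neighbors(self, small_expr):
        nbrs = NeighborSets(objective_neighbors=[np.array([0])] * 6,
                            covariance_neighbors=[np.array([0])] * 6)
        with pytest.raises(ValueError, match="at least 2"):
            weighted_kendall_tau(small_expr, uniform_kernel(6), nbrs, 0)


class TestTauToCovariance:
    def test_endpoints(self):
        tau = np.array([[0.3, 1.0], [1.0, 0.3]])
        S = tau_to_covariance(tau)
        np.testing.assert_allclose(S[0, 1], 1.0)
        np.testing.assert_allclose(np.diag(S), 1.0)
        S0 = tau_to_covariance(np.zeros((3, 3)))
        assert (S0[~np.eye(3, dtype=bool)] == 0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            tau_to_covariance(np.array([[0.0, 1.1], [1.1, 0.0]]))

    def test_sine_transform_recovers_gaussian_correlation(self):
        # Greiner's identity: for bivariate Gaussian, rho = sin(pi/2 * tau)
        rng = np.random.default_rng(42)
        rho = 0.6
        L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        Z = rng.standard_normal((800, 2)) @ L.T + 10.0
        expr = expr_from(Z)
        tau = weighted_kendall_tau(expr, uniform_kernel(800), all_neighbors(800), 0)
        S = tau_to_covariance(tau)
        assert abs(S[0, 1] - rho) < 0.08


class TestProjectPositiveDefinite:
    def test_identity_untouched(self):
        np.testing.assert_array_equal(project_positive_definite(np.eye(4)),
                                      np.eye(4))

    def test_negative_eigenvalue_replaced(self):
        S = np.diag([2.0, -0.5])
        out = project_positive_definite(S, epsilon=1e-3)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(out)),
                                   [1e-3, 2.0], atol=1e-12)

    def test_random_indefinite(self, rng):
        A = rng.standard_normal((5, 5))
        S = (A + A.T) / 2
        out = project_positive_definite(S)
        w, V = np.linalg.eigh(S)
        assert np.linalg.eigvalsh(out)[0] >= 1e-3 - 1e-9
        # action preserved on the span of positive-eigenvalue eigenvectors
        pos = V[:, w > 0]
        np.testing.assert_allclose(out @ pos, S @ pos, atol=1e-9)

    def test_idempotent(self, rng):
        A = rng.standard_normal((6, 6))
        S = (A + A.T) / 2
        once = project_positive_definite(S)
        np.testing.assert_allclose(project_positive_definite(once), once,
                                   atol=1e-10)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            project_positive_definite(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestAllCellCovariances:
    def test_composition_matches_single_ops(self, small_expr):
        kern = uniform_kernel(6)
        nbrs = all_neighbors(6)
        cov = all_cell_covariances(small_expr, kern, nbrs, store_tau=True)
        for j in range(6):
            tau = weighted_kendall_tau(small_expr, kern, nbrs, j)
            expected = project_positive_definite(tau_to_covariance(tau))
            np.testing.assert_allclose(cov.Sigma[j], expected, atol=1e-12)
            np.testing.assert_allclose(cov.tau[j], tau, atol=1e-12)

    def test_identical_cells_identical_sigma(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        expr = expr_from(X)
        cov = all_cell_covariances(expr, uniform_kernel(5), all_neighbors(5))
        for j in range(1, 5):
            np.testing.assert_array_equal(cov.Sigma[j], cov.Sigma[0])

    def test_slices_positive_definite(self, small_dataset):
        cov = small_dataset["cov"]
        for j in range(cov.n_cells):
            assert np.linalg.eigvalsh(cov.Sigma[j])[0] >= 1e-3 - 1e-9
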