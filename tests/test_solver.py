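import numpy as np
import pytest
from sklearn.covariance import graphical_lasso

from cellgrn import (
    SolverConfig,
    admm_solve,
    assemble_cell_data,
    infer_all_cells,
    prior_none,
)
from cellgrn.covariance import CellCovariance
from cellgrn.kernel import KernelWeights, NeighborSets
from cellgrn.prior import CellPriorGraph

from conftest import random_pd


class TestAssembleCellData:
    def _setup(self, n, g, K, sigmas, neighborhoods):
        kern = KernelWeights(K=K, geodesic_D=np.zeros((n, n)), bandwidth=1.0,
                             knn_k=1)
        nbrs = NeighborSets(objective_neighbors=neighborhoods,
                            covariance_neighbors=neighborhoods)
        cov = CellCovariance(Sigma=np.stack(sigmas))
        return kern, nbrs, cov

    def test_self_only_neighborhood(self, rng):
        S0, S1 = random_pd(rng, 3), random_pd(rng, 3)
        kern, nbrs, cov = self._setup(2, 3, np.ones((2, 2)), [S0, S1],
                                      [np.array([0]), np.array([1])])
        Sbar, Wi = assemble_cell_data(kern, nbrs, cov, 0)
        np.testing.assert_allclose(Sbar, S0)
        assert Wi == 1.0

    def test_equal_weights_average(self, rng):
        A, B = random_pd(rng, 3), random_pd(rng, 3)
        kern, nbrs, cov = self._setup(2, 3, np.ones((2, 2)), [A, B],
                                      [np.array([0, 1])] * 2)
        Sbar, Wi = assemble_cell_data(kern, nbrs, cov, 0)
        np.testing.assert_allclose(Sbar, (A + B) / 2)
        assert Wi == 2.0

    def test_unequal_weights_match_hand_sum(self, rng):
        sigmas = [random_pd(rng, 4) for _ in range(3)]
        K = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.7], [0.2, 0.7, 1.0]])
        kern, nbrs, cov = self._setup(3, 4, K, sigmas, [np.arange(3)] * 3)
        Sbar, Wi = assemble_cell_data(kern, nbrs, cov, 1)
        w = K[1]
        expected = sum(wi * Si for wi, Si in zip(w, sigmas)) / w.sum()
        np.testing.assert_allclose(Sbar, expected, atol=1e-12)
        np.testing.assert_allclose(Wi, w.sum())


class TestAdmmSolve:
    def test_identity_data_zero_penalty(self):
        res = admm_solve(np.eye(4), None, SolverConfig(lam=0.0, tol_primal=1e-8,
                                                       tol_dual=1e-8))
        np.testing.assert_allclose(res.theta, np.eye(4), atol=1e-6)
        assert res.converged

    def test_unpenalized_solution_is_inverse(self, rng):
        S = random_pd(rng, 6)
        cfg = SolverConfig(lam=0.0, tol_primal=1e-8, tol_dual=1e-8,
                           max_iter=5000)
        res = admm_solve(S, None, cfg)
        assert np.linalg.norm(res.theta - np.linalg.inv(S)) < 1e-5

    def test_matches_graphical_lasso_oracle(self, rng):
        S = random_pd(rng, 6)
        lam = 0.1
        _, prec = graphical_lasso(S, alpha=lam, mode="lars", tol=1e-12,
                                  max_iter=2000)
        cfg = SolverConfig(lam=lam, tol_primal=1e-8, tol_dual=1e-8,
                           max_iter=20000)
        res = admm_solve(S, None, cfg)
        assert np.linalg.norm(res.theta - prec) < 1e-4

    def test_iterates_stay_positive_definite(self, rng):
        S = random_pd(rng, 5)
        res = admm_solve(S, None, SolverConfig(lam=0.2), track=True)
        assert len(res.min_eig_trace) == res.iterations
        assert min(res.min_eig_trace) > 0

    def test_objective_decreases_overall(self, rng):
        S = random_pd(rng, 5)
        res = admm_solve(S, None, SolverConfig(lam=0.1), track=True)
        assert res.objective_trace[-1] <= res.objective_trace[0]

    def test_edge_count_monotone_in_lambda(self, rng):
        S = random_pd(rng, 8)
        counts = []
        for lam in [0.01, 0.05, 0.1, 0.2, 0.4]:
            res = admm_solve(S, None, SolverConfig(lam=lam))
            counts.append(int((np.abs(res.z) > 1e-4).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mask_suppression_monotone_in_beta(self, rng):
        S = random_pd(rng, 6)
        mask = np.zeros((6, 6), dtype=int)
        mask[0, 1] = mask[1, 0] = 1
        mags = []
        for beta in [0.0, 1.0, 10.0, 100.0, 1e4]:
            res = admm_solve(S, mask, SolverConfig(lam=0.0, beta=beta))
            mags.append(abs(res.theta[0, 1]))
        assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))
        assert mags[-1] < 1e-3 * np.abs(res.theta).max()

    def test_penalty_scale_equivalence(self, rng):
        # verbatim-objective scaling with a compensated lam equals the
        # normalized solve: the argmin is invariant to positive rescaling
        S = random_pd(rng, 5)
        lam_eff = 0.1
        a = admm_solve(S, None, SolverConfig(lam=lam_eff, tol_primal=1e-8,
                                             tol_dual=1e-8))
        scale = 0.037
        b = admm_solve(S, None, SolverConfig(lam=lam_eff / scale,
                                             tol_primal=1e-8, tol_dual=1e-8),
                       penalty_scale=scale)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-6)

    def test_mask_diagonal_must_be_zero(self, rng):
        S = random_pd(rng, 3)
        with pytest.raises(ValueError, match="diagonal"):
            admm_solve(S, np.eye(3, dtype=int), SolverConfig())

    def test_asymmetric_data_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            admm_solve(np.array([[1.0, 0.2], [0.0, 1.0]]), None, SolverConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(lam=-0.1)
        with pytest.raises(ValueError):
            SolverConfig(rho=0.0)
        with pytest.raises(ValueError):
            SolverConfig(init="random")


class TestInferAllCells:
    def test_identical_cells_identical_networks(self, rng):
        from cellgrn import ExpressionMatrix, all_cell_covariances
        X = np.tile(np.abs(rng.standard_normal(5)) + 0.5, (4, 1))
        X = X * (1 + 0.0)  # identical rows
        expr = ExpressionMatrix(values=X, gene_names=[f"g{i}" for i in range(5)],
                                cell_ids=[f"c{i}" for i in range(4)])
        kern = KernelWeights(K=np.ones((4, 4)), geodesic_D=np.zeros((4, 4)),
                             bandwidth=1.0, knn_k=3)
        nbrs = NeighborSets(objective_neighbors=[np.arange(4)] * 4,
                            covariance_neighbors=[np.arange(4)] * 4)
        cov = all_cell_covariances(expr, kern, nbrs)
        tensor = infer_all_cells(expr, kern, nbrs, cov, None, SolverConfig())
        for i in range(1, 4):
            np.testing.assert_allclose(tensor.networks[i], tensor.networks[0],
                                       atol=1e-12)

    def test_large_beta_suppresses_masked_edge(self, small_dataset):
        d = small_dataset
        g = d["expr"].n_genes
        G = np.ones((1, g, g), dtype=np.uint8)
        G[0, 0, 1] = G[0, 1, 0] = 0
        priors = CellPriorGraph(G_prior=G, mode="tf")
        cfg = SolverConfig(lam=0.01, beta=1e4)
        tensor = infer_all_cells(d["expr"], d["kernel"], d["neighbors"],
                                 d["cov"], priors, cfg)
        for i in range(tensor.n_cells):
            T = tensor.networks[i]
            assert abs(T[0, 1]) < 1e-3 * np.abs(T).max()

    def test_full_pipeline_networks_all_pd(self, small_dataset):
        d = small_dataset
        priors = prior_none(d["expr"].n_cells, d["expr"].n_genes)
        tensor = infer_all_cells(d["expr"], d["kernel"], d["neighbors"],
                                 d["cov"], priors, SolverConfig(lam=0.05))
        for i in range(tensor.n_cells):
            assert np.linalg.eigvalsh(tensor.networks[i])[0] > 0

    def test_prior_slice_count_validated(self, small_dataset):
        d = small_dataset
        g = d["expr"].n_genes
        bad = CellPriorGraph(G_prior=np.ones((2, g, g), dtype=np.uint8),
                             mode="none")
        with pytest.raises(ValueError, match="slice"):
            infer_all_cells(d["expr"], d["kernel"], d["neighbors"], d["cov"],
                            bad, SolverConfig())
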