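"""GMRF densities and exact conditionals against dense Gaussian oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from carmap.gmrf import (
    Gaussian,
    LinRegImputationModel,
    MCARModel,
    ProperCARModel,
    car_logpdf,
    conditional_missing,
    fit_linreg_imputation,
    linreg_imputation,
    mcar_conditional_missing,
    mcar_joint_precision,
)
from carmap.graph import from_edge_list, grid

from conftest import dense_gaussian_conditional, make_random_connected_graph


def dense_cov(model: ProperCARModel) -> np.ndarray:
    return np.linalg.inv(model.precision().toarray())


class TestCarLogpdf:
    def test_independent_limit_small_rho(self):
        g = from_edge_list([("a", "b")])
        m = ProperCARModel(alpha=1.5, rho=1e-9, tau_c=2.0, W_scaled=g)
        x = np.array([0.3, 2.1])
        from scipy.stats import norm
        expected = norm.logpdf(x, loc=1.5, scale=1 / np.sqrt(2.0)).sum()
        assert car_logpdf(x, m) == pytest.approx(expected, abs=1e-6)

    def test_matches_dense_mvn_oracle_on_path(self):
        g = from_edge_list([(1, 2), (2, 3)])
        m = ProperCARModel(alpha=0.4, rho=0.5, tau_c=1.0, W_scaled=g)
        x = np.array([0.1, -0.7, 1.3])
        oracle = multivariate_normal(mean=0.4 * np.ones(3),
                                     cov=dense_cov(m)).logpdf(x)
        assert car_logpdf(x, m) == pytest.approx(oracle, abs=1e-10)

    def test_translation_invariance(self):
        g = grid(3, 3)
        x = np.random.default_rng(1).standard_normal(9)
        a = car_logpdf(x, ProperCARModel(0.0, 0.6, 1.4, g))
        b = car_logpdf(x + 5.0, ProperCARModel(5.0, 0.6, 1.4, g))
        assert b == pytest.approx(a, abs=1e-10)

    def test_density_integrates_to_one_two_nodes(self):
        from scipy.integrate import dblquad

        g = from_edge_list([("a", "b")])
        m = ProperCARModel(alpha=0.0, rho=0.8, tau_c=1.0, W_scaled=g)
        val, err = dblquad(
            lambda y, x: np.exp(car_logpdf(np.array([x, y]), m)),
            -15, 15, -15, 15, epsabs=1e-9)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        g = grid(2, 2)
        with pytest.raises(ValueError):
            ProperCARModel(0.0, 1.2, 1.0, g)
        with pytest.raises(ValueError):
            ProperCARModel(0.0, 0.5, -1.0, g)


class TestConditionalMissing:
    def test_rho_zero_limit_no_borrowing(self):
        g = grid(2, 3)
        m = ProperCARModel(alpha=2.0, rho=1e-12, tau_c=4.0, W_scaled=g)
        cond = conditional_missing(np.zeros(6), [1, 4], m)
        assert np.allclose(cond.mean, 2.0, atol=1e-10)
        assert np.allclose(cond.cov, np.eye(2) / 4.0, atol=1e-10)

    def test_two_node_hand_solution(self):
        # single edge: W_scaled off-diagonals are 1; node 2 missing,
        # alpha=0, rho=0.5, tau_c=2 -> joint precision [[2,-1],[-1,2]],
        # conditional mean 0.5 x1, conditional variance 1/2
        g = from_edge_list([("a", "b")])
        m = ProperCARModel(alpha=0.0, rho=0.5, tau_c=2.0, W_scaled=g)
        x = np.array([0.8, np.nan])
        cond = conditional_missing(x, [1], m)
        assert cond.mean[0] == pytest.approx(0.4, abs=1e-12)
        assert cond.cov[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_dense_conditioning_on_grid(self, rng):
        g = grid(5, 5)
        m = ProperCARModel(alpha=0.7, rho=0.85, tau_c=1.3, W_scaled=g)
        x = rng.standard_normal(25)
        mis = np.array([2, 7, 11, 24])
        obs = np.setdiff1d(np.arange(25), mis)
        cond = conditional_missing(x, mis, m)
        mean_o, cov_o = dense_gaussian_conditional(
            0.7 * np.ones(25), dense_cov(m), mis, obs, x[obs])
        assert np.allclose(cond.mean, mean_o, atol=1e-8)
        assert np.allclose(cond.cov, cov_o, atol=1e-8)

    def test_matches_dense_conditioning_random_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 37))
            g = make_random_connected_graph(rng, n)
            m = ProperCARModel(alpha=float(rng.normal()),
                               rho=float(rng.uniform(0.05, 0.95)),
                               tau_c=float(rng.uniform(0.2, 5.0)), W_scaled=g)
            x = rng.standard_normal(n)
            n_mis = int(rng.integers(1, max(2, n // 3)))
            mis = rng.choice(n, size=n_mis, replace=False)
            obs = np.setdiff1d(np.arange(n), mis)
            cond = conditional_missing(x, mis, m)
            mean_o, cov_o = dense_gaussian_conditional(
                m.alpha * np.ones(n), dense_cov(m), mis, obs, x[obs])
            assert np.allclose(cond.mean, mean_o, atol=1e-8)
            assert np.allclose(cond.cov, cov_o, atol=1e-8)

    def test_reconditioning_is_a_fixed_point(self, rng):
        # conditioning on values drawn at the conditional mean leaves the
        # conditional unchanged (mean/cov fixed point of the Gibbs map)
        g = grid(4, 4)
        m = ProperCARModel(alpha=0.0, rho=0.9, tau_c=1.0, W_scaled=g)
        x = rng.standard_normal(16)
        mis = np.array([3, 8])
        cond1 = conditional_missing(x, mis, m)
        x2 = x.copy()
        x2[mis] = cond1.mean
        cond2 = conditional_missing(x2, mis, m)
        assert np.allclose(cond1.mean, cond2.mean, atol=1e-12)
        assert np.allclose(cond1.cov, cond2.cov, atol=1e-12)

    def test_degenerate_requests_rejected(self):
        g = grid(2, 2)
        m = ProperCARModel(0.0, 0.5, 1.0, g)
        with pytest.raises(ValueError, match="all nodes"):
            conditional_missing(np.zeros(4), [0, 1, 2, 3], m)
        empty = conditional_missing(np.zeros(4), [], m)
        assert empty.mean.size == 0


class TestMCAR:
    def test_k1_reduces_to_proper_car(self):
        g = grid(3, 3)
        tau_c = 2.5
        mc = MCARModel(alphas=[0.0], rho=0.7, Lambda=[[tau_c]], W_scaled=g)
        pc = ProperCARModel(alpha=0.0, rho=0.7, tau_c=tau_c, W_scaled=g)
        assert np.allclose(mcar_joint_precision(mc).toarray(),
                           pc.precision().toarray(), atol=1e-12)

    def test_diagonal_lambda_gives_independent_fields(self):
        g = grid(3, 3)
        mc = MCARModel(alphas=[0.0, 0.0], rho=0.6,
                       Lambda=np.diag([1.0, 3.0]), W_scaled=g)
        cov = np.linalg.inv(mcar_joint_precision(mc).toarray())
        n = 9
        assert np.allclose(cov[:n, n:], 0.0, atol=1e-10)

    def test_kron_matches_explicit_block_assembly(self):
        g = from_edge_list([(1, 2), (2, 3)])
        Lam = np.array([[2.0, 0.5], [0.5, 1.5]])
        mc = MCARModel(alphas=[0.1, -0.2], rho=0.4, Lambda=Lam, W_scaled=g)
        R = np.eye(3) - 0.4 * g.W_scaled.toarray()
        explicit = np.block([[Lam[0, 0] * R, Lam[0, 1] * R],
                             [Lam[1, 0] * R, Lam[1, 1] * R]])
        assert np.allclose(mcar_joint_precision(mc).toarray(), explicit,
                           atol=1e-12)

    def test_diagonal_lambda_conditional_separates(self, rng):
        g = grid(3, 3)
        lam = np.diag([1.2, 0.8])
        mc = MCARModel(alphas=[0.3, -0.1], rho=0.75, Lambda=lam, W_scaled=g)
        X = rng.standard_normal((9, 2))
        cells = np.array([[2, 0], [5, 1]])
        joint = mcar_conditional_missing(X, cells, mc)
        for j, (site, cov_idx) in enumerate(cells):
            pc = ProperCARModel(alpha=mc.alphas[cov_idx], rho=0.75,
                                tau_c=lam[cov_idx, cov_idx], W_scaled=g)
            single = conditional_missing(X[:, cov_idx], [site], pc)
            assert joint.mean[j] == pytest.approx(single.mean[0], abs=1e-10)
            assert joint.cov[j, j] == pytest.approx(single.cov[0, 0], abs=1e-10)
        assert abs(joint.cov[0, 1]) < 1e-10

    def test_matches_dense_conditioning(self, rng):
        g = from_edge_list([(0, 1), (1, 2), (2, 3), (3, 0)])
        Lam = np.array([[2.0, 0.7], [0.7, 1.1]])
        mc = MCARModel(alphas=[0.5, -0.5], rho=0.6, Lambda=Lam, W_scaled=g)
        X = rng.standard_normal((4, 2))
        cells = np.array([[1, 0], [1, 1], [3, 1]])
        stacked = cells[:, 1] * 4 + cells[:, 0]
        cond = mcar_conditional_missing(X, cells, mc)
        cov_joint = np.linalg.inv(mcar_joint_precision(mc).toarray())
        mu = np.repeat(mc.alphas, 4)
        obs = np.setdiff1d(np.arange(8), stacked)
        z = X.ravel(order="F")
        mean_o, cov_o = dense_gaussian_conditional(mu, cov_joint, stacked,
                                                   obs, z[obs])
        assert np.allclose(cond.mean, mean_o, atol=1e-8)
        assert np.allclose(cond.cov, cov_o, atol=1e-8)

    def test_no_missing_cells_is_noop(self):
        g = grid(2, 2)
        mc = MCARModel(alphas=[0.0], rho=0.5, Lambda=[[1.0]], W_scaled=g)
        cond = mcar_conditional_missing(np.zeros((4, 1)), np.empty((0, 2)), mc)
        assert cond.mean.size == 0

    def test_non_pd_lambda_rejected(self):
        g = grid(2, 2)
        with pytest.raises(ValueError, match="positive definite"):
            MCARModel(alphas=[0, 0], rho=0.5,
                      Lambda=[[1.0, 2.0], [2.0, 1.0]], W_scaled=g)


class TestLinRegImputation:
    def test_high_precision_collapses_to_plugin_mean(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        model = LinRegImputationModel(beta=[1.0, 2.0], tau_c=1e12)
        x = X @ model.beta
        x[[2, 7]] = np.nan
        cond = linreg_imputation(X, x, model)
        draws = Gaussian(cond.mean, cond.cov).sample(rng, size=50)
        assert np.max(np.abs(draws - X[[2, 7]] @ np.array([1.0, 2.0]))) < 1e-5

    def test_intercept_only_design(self):
        X = np.ones((5, 1))
        model = LinRegImputationModel(beta=[3.3], tau_c=2.0)
        x = np.array([3.0, np.nan, 3.5, np.nan, 3.2])
        cond = linreg_imputation(X, x, model)
        assert np.allclose(cond.mean, 3.3)
        assert np.allclose(cond.cov, np.eye(2) / 2.0)

    def test_rank_deficient_rejected(self):
        X = np.ones((6, 2))  # duplicated column
        with pytest.raises(ValueError, match="rank"):
            fit_linreg_imputation(X, np.arange(6.0))

    def test_imputation_rmse_improves_with_precision(self, rng):
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        beta = np.array([0.5, 1.0, -2.0])
        rmses = []
        for sigma in (2.0, 0.5, 0.05):
            x = X @ beta + sigma * rng.standard_normal(200)
            truth = x.copy()
            x[:40] = np.nan
            model = fit_linreg_imputation(X, x)
            cond = linreg_imputation(X, x, model)
            rmses.append(np.sqrt(np.mean((cond.mean - truth[:40]) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]
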