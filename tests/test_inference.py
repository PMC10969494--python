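"""MCMC sampler correctness: exact subcases, determinism, calibration."""

import numpy as np
import pytest

from carmap.data import AreaTable
from carmap.graph import from_edge_list, grid
from carmap.inference import (
    FitConfig,
    FitError,
    ModelSpec,
    fit,
    posterior_summary,
    predict_missing_responses,
)
from carmap.synthetic import SyntheticConfig, make_dataset, small_config

from conftest import dense_gaussian_conditional, make_random_connected_graph


def intercept_only_table(rng, graph, pop=200.0, rate=0.1):
    y = rng.poisson(pop * rate, size=graph.n).astype(float)
    return AreaTable(ids=np.asarray(graph.node_ids), y=y,
                     population=np.full(graph.n, pop), X=np.empty((graph.n, 0)))


def quadrature_posterior(y, N, prior_sd=100.0):
    """Exact intercept-only Poisson posterior moments by dense quadrature."""
    sy, sN = y.sum(), N.sum()
    mle = np.log(sy / sN)
    b = np.linspace(mle - 1.5, mle + 1.5, 20001)
    logpost = sy * b - sN * np.exp(b) - 0.5 * (b / prior_sd) ** 2
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = float(w @ b)
    sd = float(np.sqrt(w @ (b - mean) ** 2))
    return mean, sd


class TestExactSubcases:
    def test_intercept_only_matches_quadrature_posterior(self, rng):
        g = grid(6, 10)
        table = intercept_only_table(rng, g)
        spec = ModelSpec(family="poisson", spatial=False, imputation="none")
        cfg = FitConfig(n_iter=4000, n_burnin=1000, thin=1, n_chains=2, seed=3)
        s = fit(table, g, spec, cfg)
        b0 = s.stacked("beta")[:, 0]
        mean_q, sd_q = quadrature_posterior(table.y, table.population)
        mcse = b0.std() / np.sqrt(50.0)  # conservative ESS lower bound
        assert b0.mean() == pytest.approx(mean_q, abs=4 * mcse)
        assert b0.std() == pytest.approx(sd_q, rel=0.25)
        # closed-form MLE check on the rate scale
        rate_mle = table.y.sum() / table.population.sum()
        assert np.exp(b0.mean()) == pytest.approx(rate_mle, rel=4 * mcse + 0.02)

    def test_car_full_conditional_matches_dense_conditioning(self, rng):
        # the Besag conditional the theta update uses:
        # theta_i | rest ~ N(rho/m_i sum_j w_ij theta_j, 1/(tau m_i))
        for _ in range(5):
            n = int(rng.integers(5, 25))
            g = make_random_connected_graph(rng, n)
            tau, rho = float(rng.uniform(0.5, 3)), float(rng.uniform(0.1, 0.95))
            Q = tau * (np.diag(g.M) - rho * g.W.toarray())
            cov = np.linalg.inv(Q)
            theta = rng.standard_normal(n)
            i = int(rng.integers(n))
            rest = np.setdiff1d(np.arange(n), [i])
            mean_o, cov_o = dense_gaussian_conditional(
                np.zeros(n), cov, np.array([i]), rest, theta[rest])
            mean_f = rho * (g.W.toarray()[i] @ theta) / g.M[i]
            var_f = 1.0 / (tau * g.M[i])
            assert mean_f == pytest.approx(mean_o[0], abs=1e-8)
            assert var_f == pytest.approx(cov_o[0, 0], abs=1e-8)


class TestDeterminism:
    def test_identical_seed_identical_chains(self):
        ds = make_dataset(small_config(nrows=8, ncols=8), seed=5)
        spec = ModelSpec(family="poisson", spatial=True, imputation="mcar")
        cfg = FitConfig(n_iter=600, n_burnin=300, thin=2, n_chains=1, seed=9)
        s1 = fit(ds.table, ds.graph, spec, cfg)
        s2 = fit(ds.table, ds.graph, spec, cfg)
        for name in s1.draws:
            assert np.array_equal(s1.draws[name], s2.draws[name]), name

    def test_different_seeds_differ(self):
        ds = make_dataset(small_config(nrows=8, ncols=8), seed=5)
        spec = ModelSpec(spatial=True, imputation="mcar")
        s1 = fit(ds.table, ds.graph, spec,
                 FitConfig(n_iter=600, n_burnin=300, n_chains=1, seed=1))
        s2 = fit(ds.table, ds.graph, spec,
                 FitConfig(n_iter=600, n_burnin=300, n_chains=1, seed=2))
        assert not np.array_equal(s1.draws["beta"], s2.draws["beta"])


class TestSpecValidation:
    def test_nonspatial_mcar_is_invalid(self):
        with pytest.raises(ValueError, match="linreg"):
            ModelSpec(spatial=False, imputation="mcar")

    def test_graph_data_mismatch_rejected(self):
        ds = make_dataset(small_config(nrows=6, ncols=6), seed=1)
        with pytest.raises(FitError):
            fit(ds.table, grid(5, 5), ModelSpec(imputation="none"))

    def test_disconnected_graph_needs_flag(self, rng):
        g = from_edge_list([("a", "b"), ("c", "d")])
        t = AreaTable(ids=["a", "b", "c", "d"],
                      y=np.array([3.0, 4.0, 5.0, 6.0]),
                      population=np.full(4, 50.0), X=np.empty((4, 0)))
        with pytest.raises(FitError, match="components"):
            fit(t, g, ModelSpec(imputation="none"),
                FitConfig(n_iter=200, n_burnin=100, n_chains=1))
        s = fit(t, g, ModelSpec(imputation="none", allow_components=True),
                FitConfig(n_iter=200, n_burnin=100, n_chains=1, seed=1))
        assert np.isfinite(s.stacked("beta")).all()

    def test_no_imputation_drops_incomplete_units_by_default(self):
        ds = make_dataset(small_config(nrows=10, ncols=10,
                                       p_missing_x=np.array([0.05, 0, 0, 0])),
                          seed=7)
        n_incomplete = int(np.isnan(ds.table.X).any(axis=1).sum())
        assert n_incomplete > 0
        cfg = FitConfig(n_iter=300, n_burnin=150, n_chains=1, seed=0)
        dropped = fit(ds.table, ds.graph,
                      ModelSpec(spatial=False, imputation="none"), cfg)
        assert dropped.data["y"].size == 100 - n_incomplete
        zeroed = fit(ds.table, ds.graph,
                     ModelSpec(spatial=False, imputation="none",
                               zero_fill_missing=True), cfg)
        assert zeroed.data["y"].size == 100


class TestPosteriorSummary:
    def test_moments_match_independent_recomputation(self):
        ds = make_dataset(small_config(nrows=8, ncols=8), seed=2)
        s = fit(ds.table, ds.graph, ModelSpec(imputation="mcar"),
                FitConfig(n_iter=800, n_burnin=400, thin=2, n_chains=2, seed=4))
        summ = posterior_summary(s).set_index("parameter")
        beta = s.stacked("beta")
        for j, name in enumerate(["(intercept)"] + s.data["covariate_names"]):
            assert summ.loc[name, "mean"] == pytest.approx(
                float(np.mean(beta[:, j])), abs=1e-12)
            assert summ.loc[name, "sd"] == pytest.approx(
                float(np.std(beta[:, j], ddof=1)), abs=1e-12)
            assert summ.loc[name, "2.5%"] == pytest.approx(
                float(np.quantile(beta[:, j], 0.025)), abs=1e-12)

    def test_credible_flag_tracks_interval(self):
        ds = make_dataset(small_config(nrows=8, ncols=8), seed=2)
        s = fit(ds.table, ds.graph, ModelSpec(imputation="mcar"),
                FitConfig(n_iter=800, n_burnin=400, thin=2, n_chains=1, seed=4))
        summ = posterior_summary(s)
        for _, row in summ.iterrows():
            assert row["credible"] == (row["2.5%"] > 0 or row["97.5%"] < 0)


class TestMissingResponses:
    def test_predictive_draws_are_counts_and_cover_truth(self):
        # at a missing-response unit theta_i is informed only through its
        # neighbours, so the predictive mean shrinks toward the neighbourhood
        # level; the meaningful requirement is interval calibration
        cfg_s = small_config(nrows=12, ncols=12, p_missing_y=0.3,
                             p_missing_x=np.zeros(4))
        ds = make_dataset(cfg_s, seed=13)
        assert ds.table.missing_y.sum() > 20
        s = fit(ds.table, ds.graph, ModelSpec(imputation="none"),
                FitConfig(n_iter=1500, n_burnin=600, thin=2, n_chains=1, seed=6))
        d = s.stacked("y_mis")
        assert np.all(d >= 0)
        assert np.all(d == np.round(d))
        pred = predict_missing_responses(s, level=0.9)
        truth = ds.table.y_true[ds.table.missing_y]
        covered = np.mean((truth >= pred["5%"]) & (truth <= pred["95%"]))
        assert covered > 0.75
        corr = np.corrcoef(np.log1p(pred["predictive_mean"]),
                           np.log1p(truth))[0, 1]
        assert corr > 0.3

    def test_error_when_nothing_missing(self, rng):
        g = grid(4, 4)
        t = intercept_only_table(rng, g)
        s = fit(t, g, ModelSpec(spatial=False, imputation="none"),
                FitConfig(n_iter=300, n_burnin=150, n_chains=1, seed=0))
        with pytest.raises(ValueError, match="missing-response"):
            predict_missing_responses(s)


class TestChainQuality:
    def test_ess_grows_with_chain_length(self, rng):
        g = grid(5, 8)
        table = intercept_only_table(rng, g)
        spec = ModelSpec(spatial=False, imputation="none")
        ess = []
        for n_iter in (400, 1600, 6400):
            s = fit(table, g, spec,
                    FitConfig(n_iter=n_iter, n_burnin=n_iter // 4, thin=1,
                              n_chains=1, seed=5))
            ess.append(float(s.convergence_table()["ess"].iloc[0]))
        assert ess[2] > 2 * ess[0]

    def test_mcar_imputation_consistent_with_oracle_covariates(self):
        # with ~1% missingness the imputed fit should agree with the fit on
        # the complete design within the posterior uncertainty
        cfg_s = small_config(nrows=10, ncols=10,
                             p_missing_x=np.full(4, 0.01), p_missing_y=0.0)
        ds = make_dataset(cfg_s, seed=21)
        cfg = FitConfig(n_iter=2000, n_burnin=800, thin=2, n_chains=1, seed=8)
        imput = fit(ds.table, ds.graph, ModelSpec(imputation="mcar"), cfg)
        complete = AreaTable(ids=ds.table.ids, y=ds.table.y,
                             population=ds.table.population,
                             X=ds.table.X_true,
                             covariate_names=ds.table.covariate_names)
        oracle = fit(complete, ds.graph, ModelSpec(imputation="none"), cfg)
        b_i = imput.stacked("beta")
        b_o = oracle.stacked("beta")
        for j in range(1, b_i.shape[1]):
            gap = abs(b_i[:, j].mean() - b_o[:, j].mean())
            pooled = np.sqrt(b_i[:, j].std() ** 2 + b_o[:, j].std() ** 2)
            assert gap < 2.0 * pooled
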