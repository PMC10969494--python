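"""Full-Bayes MCMC for the joint disease-mapping model.

The target posterior is that of the hierarchical model

    y_i | eta_i       ~ Poisson(exp(eta_i))  or  NB(r, exp(eta_i))
    eta_i             = beta_0 + x_i' beta + log N_i + theta_i
    theta | tau, rho  ~ N(0, [tau (M - rho W)]^{-1})          (proper CAR)
    x cells missing   ~ jointly Gaussian with the observed cells under the
                        multivariate CAR (spatial) or a linear regression on
                        the fully observed covariates (nonspatial)

with missing responses handled through their posterior predictive
distribution.  Inference is by adaptive Metropolis-within-Gibbs:

* ``beta`` — blockwise adaptive random-walk Metropolis (empirical-covariance
  proposal, scale tuned to ~23% acceptance, frozen at burn-in end);
* ``theta`` — colour-blocked single-site Metropolis using the CAR full
  conditional N(rho * mean of neighbours' theta, 1/(tau m_i)) as the prior
  factor; same-colour units are non-adjacent so a whole colour class is
  updated in one vectorised step;
* ``tau`` (and the linear-imputation ``tau_c``) — conjugate gamma Gibbs;
* ``rho``, ``rho_c`` — Metropolis on the logit scale, log-determinants from
  precomputed eigenvalues;
* ``r`` — Metropolis on the log scale;
* missing covariate cells — exact GMRF / linear-regression full-conditional
  proposals, Metropolis-corrected by the outcome likelihood of the unit;
* missing responses — drawn from the outcome family at current parameters.

All randomness flows from a single seed; identical seed and configuration
reproduce chains bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import wishart

from .data import AreaTable
from .graph import AdjacencyGraph
from .outcomes import family_logpmf

__all__ = [
    "ModelSpec", "FitConfig", "PosteriorSamples", "fit",
    "posterior_summary", "predict_missing_responses",
]


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """What to fit: outcome family, spatial effect, imputation mode."""

    family: str = "poisson"          # "poisson" | "negbinom"
    spatial: bool = True
    imputation: str = "mcar"         # "mcar" | "linreg" | "none"
    standardize: bool = True
    zero_fill_missing: bool = False  # imputation="none": substitute raw zeros
                                     # instead of dropping incomplete units
    allow_components: bool = False   # permit a disconnected adjacency graph

    def __post_init__(self):
        if self.family not in ("poisson", "negbinom"):
            raise ValueError("family must be 'poisson' or 'negbinom'")
        if self.imputation not in ("mcar", "linreg", "none"):
            raise ValueError("imputation must be 'mcar', 'linreg' or 'none'")
        if self.imputation == "mcar" and not self.spatial:
            raise ValueError(
                "MCAR imputation requires the spatial model; use 'linreg' "
                "for nonspatial variants"
            )

    @property
    def label(self) -> str:
        fam = {"poisson": "Poisson", "negbinom": "NB"}[self.family]
        sp_ = "spatial" if self.spatial else "nonspatial"
        imp = {"mcar": "MCAR imputation", "linreg": "linreg imputation",
               "none": "no imputation"}[self.imputation]
        return f"{sp_} {fam} ({imp})"


@dataclass
class FitConfig:
    """Chain lengths, priors and proposal-adaptation settings."""

    n_iter: int = 20000
    n_burnin: int = 10000
    thin: int = 5
    n_chains: int = 4
    seed: int = 0

    beta_prior_sd: float = 100.0
    tau_prior: tuple = (1.0, 5e-5)        # gamma(shape, rate) for tau, tau_c
    r_prior: tuple = (1.0, 0.01)          # gamma prior on r (log-scale walk)
    alpha_prior_prec: float = 1e-6
    # Lambda ~ Wishart(identity scale, K + 1 df)

    store_theta: bool = True
    center_threshold: float = 0.99        # sum-to-zero recentring when rho drifts
    rhat_warn: float = 1.05

    def __post_init__(self):
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("need n_chains >= 1 and thin >= 1")

    @property
    def n_store(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """MCMC draws with shape (n_chains, n_draws, ...), plus the effective
    data the model was fitted to (after any unit drops and standardization)."""

    spec: ModelSpec
    config: FitConfig
    draws: dict
    data: dict
    accept: dict = dc_field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def n_draws_total(self) -> int:
        return self.draws["beta"].shape[0] * self.draws["beta"].shape[1]

    @property
    def loglik_pointwise(self) -> np.ndarray:
        """Per-draw per-observed-unit log likelihood, stacked over chains."""
        return self.stacked("loglik")

    @property
    def fitted_mean(self) -> np.ndarray:
        """Posterior-mean expected count per unit."""
        return self.data["mu_sum"] / self.n_draws_total

    def _design_at(self, x_cells: np.ndarray) -> np.ndarray:
        Xs = self.data["Xs"].copy()
        cells = self.data["miss_cells"]
        if len(cells):
            Xs[cells[:, 0], cells[:, 1]] = x_cells
        return Xs

    def loglik_at_posterior_mean(self) -> np.ndarray:
        """Pointwise log likelihood at the posterior mean of every parameter
        entering the likelihood (the DIC plug-in)."""
        beta = self.stacked("beta").mean(axis=0)
        theta = self.data["theta_sum"] / self.n_draws_total
        cells = self.stacked("x_cells").mean(axis=0) if "x_cells" in self.draws \
            else np.empty(0)
        Xs = self._design_at(cells)
        obs = self.data["obs"]
        eta = beta[0] + Xs @ beta[1:] + self.data["offset"] + theta
        mu = np.exp(eta[obs])
        r = float(self.stacked("r").mean()) if "r" in self.draws else None
        return family_logpmf(self.spec.family, self.data["y"][obs], mu, r)

    # -- convergence --------------------------------------------------------

    def convergence_table(self) -> pd.DataFrame:
        import arviz as az

        rows = []
        for name, idx_names in self._scalar_params():
            arr = self.draws[name]
            for j, pname in enumerate(idx_names):
                a = arr[..., j] if arr.ndim == 3 else arr
                if a.shape[0] == 1:  # split the single chain for R-hat
                    half = a.shape[1] // 2
                    a = np.stack([a[0, :half], a[0, half:2 * half]])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rhat = float(az.rhat(a.astype(float)))
                    ess = float(az.ess(a.astype(float)))
                rows.append({"parameter": pname, "rhat": rhat, "ess": ess})
        return pd.DataFrame(rows)

    def _scalar_params(self):
        names = ["(intercept)"] + list(self.data["covariate_names"])
        yield "beta", names
        if "tau" in self.draws:
            yield "tau", ["tau"]
        if "rho" in self.draws:
            yield "rho", ["rho"]
        if "r" in self.draws:
            yield "r", ["r"]
        if "rho_c" in self.draws:
            yield "rho_c", ["rho_c"]


# ---------------------------------------------------------------------------
# summaries


def _summary_rows(draws_2d: np.ndarray, names, level: float):
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for j, name in enumerate(names):
        d = draws_2d[:, j]
        lo, hi = np.quantile(d, [lo_q, hi_q])
        rows.append({
            "parameter": name, "mean": d.mean(), "sd": d.std(ddof=1),
            f"{100 * lo_q:g}%": lo, f"{100 * hi_q:g}%": hi,
            "credible": bool(lo > 0 or hi < 0),
        })
    return rows


def posterior_summary(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter posterior mean, SD and equal-tailed credible interval.

    A regression coefficient is flagged ``credible`` when its interval
    excludes zero.  When covariates were standardized before fitting, raw-
    scale coefficients (per original covariate unit) are reported alongside.
    """
    if samples.n_draws_total == 0:
        raise ValueError("empty sample set")
    names = ["(intercept)"] + list(samples.data["covariate_names"])
    beta = samples.stacked("beta")
    rows = _summary_rows(beta, names, level)
    if samples.spec.standardize and len(names) > 1:
        sds = samples.data["x_sds"]
        means = samples.data["x_means"]
        raw = beta[:, 1:] / sds[None, :]
        raw0 = beta[:, 0] - (beta[:, 1:] * (means / sds)[None, :]).sum(axis=1)
        rows += _summary_rows(raw0[:, None], ["(intercept, raw scale)"], level)
        rows += _summary_rows(raw, [f"{n} (raw scale)" for n in names[1:]], level)
    for name, label in (("tau", "tau"), ("rho", "rho"), ("r", "r"),
                        ("rho_c", "rho_c")):
        if name in samples.draws:
            rows += _summary_rows(samples.stacked(name)[:, None], [label], level)
    df = pd.DataFrame(rows)
    conv = samples.convergence_table().set_index("parameter")
    df = df.join(conv, on="parameter")
    return df


def predict_missing_responses(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Posterior predictive mean, SD and interval per missing-response unit."""
    if "y_mis" not in samples.draws or samples.draws["y_mis"].shape[-1] == 0:
        raise ValueError("model was fitted without missing-response units")
    d = samples.stacked("y_mis")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo, hi = np.quantile(d, [lo_q, hi_q], axis=0)
    return pd.DataFrame({
        "id": samples.data["miss_y_ids"],
        "predictive_mean": d.mean(axis=0),
        "predictive_sd": d.std(ddof=1, axis=0),
        f"{100 * lo_q:g}%": lo,
        f"{100 * hi_q:g}%": hi,
    })


# ---------------------------------------------------------------------------
# fitting


def _glm_init(y, D, offset, max_iter=25):
    """IRLS for the Poisson GLM: starting values + Fisher-based proposal."""
    n, p = D.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.5)) - np.log(np.exp(offset).mean())
    for _ in range(max_iter):
        eta = np.clip(D @ beta + offset, -30, 30)
        mu = np.exp(eta)
        Wd = mu
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-10)
        A = D.T @ (Wd[:, None] * D) + 1e-8 * np.eye(p)
        b_new = np.linalg.solve(A, D.T @ (Wd * z))
        if np.max(np.abs(b_new - beta)) < 1e-8:
            beta = b_new
            break
        beta = b_new
    eta = np.clip(D @ beta + offset, -30, 30)
    mu = np.exp(eta)
    fisher = D.T @ (mu[:, None] * D) + 1e-8 * np.eye(p)
    return beta, np.linalg.inv(fisher)


def _prepare(data: AreaTable, graph: AdjacencyGraph, spec: ModelSpec):
    """Validate, optionally drop incomplete units, standardize covariates."""
    data.validate()
    if graph.n != data.n:
        raise FitError("graph node count does not match the data table")
    if list(map(str, graph.node_ids)) != list(map(str, data.ids)):
        raise FitError("graph node order does not match the data table IDs")
    if spec.spatial and not graph.is_connected and not spec.allow_components:
        raise FitError(
            f"adjacency graph has {graph.n_components} components; pass "
            "allow_components=True to fit a block-diagonal CAR"
        )
    X = data.X.copy()
    y = data.y.copy()
    keep = np.arange(data.n)
    if spec.imputation == "none" and np.isnan(X).any():
        if spec.zero_fill_missing:
            X = np.where(np.isnan(X), 0.0, X)  # strict-replication zero fill
        else:
            keep = np.flatnonzero(~np.isnan(X).any(axis=1))
            if keep.size == 0:
                raise FitError("no units with complete covariates remain")
            X, y = X[keep], y[keep]
            graph = graph.subset(keep) if spec.spatial else graph.subset(
                keep, allow_isolated=True)
    population = data.population[keep]
    ids = data.ids[keep]
    if spec.standardize and X.shape[1]:
        means = np.nanmean(X, axis=0)
        sds = np.nanstd(X, axis=0, ddof=0)
        if (sds == 0).any():
            raise FitError("constant covariate cannot be standardized")
        Xs = (X - means) / sds
    else:
        means = np.zeros(X.shape[1])
        sds = np.ones(X.shape[1])
        Xs = X
    return graph, ids, y, population, Xs, means, sds, keep


def fit(
    data: AreaTable,
    graph: AdjacencyGraph,
    spec: ModelSpec | None = None,
    config: FitConfig | None = None,
) -> PosteriorSamples:
    """Run the MCMC and return posterior draws.

    ``data`` rows must align with ``graph`` nodes.  Missing responses are
    retained and predicted; missing covariates are imputed according to
    ``spec.imputation`` (or dropped/zero-filled for ``"none"``).
    """
    spec = spec if spec is not None else ModelSpec()
    config = config if config is not None else FitConfig()
    graph, ids, y, population, Xs, x_means, x_sds, keep = _prepare(data, graph, spec)

    n, k = Xs.shape
    obs = ~np.isnan(y)
    if not obs.any():
        raise FitError("no observed responses")
    offset = np.log(population)
    miss_cells = np.argwhere(np.isnan(Xs))
    if miss_cells.size and spec.imputation == "none":
        miss_cells = np.empty((0, 2), dtype=int)
    miss_y = np.flatnonzero(~obs)

    shared = {
        "y": y, "obs": obs, "offset": offset, "Xs": Xs,
        "x_means": x_means, "x_sds": x_sds, "ids": ids,
        "covariate_names": list(np.asarray(data.covariate_names)) if k else [],
        "miss_cells": miss_cells, "miss_y_ids": ids[miss_y],
        "kept_index": keep,
    }

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [_run_chain(spec, config, graph, shared, np.random.default_rng(s))
              for s in seeds]

    draws = {name: np.stack([c["draws"][name] for c in chains])
             for name in chains[0]["draws"]}
    shared["mu_sum"] = np.sum([c["mu_sum"] for c in chains], axis=0)
    shared["theta_sum"] = np.sum([c["theta_sum"] for c in chains], axis=0)
    accept = {name: float(np.mean([c["accept"][name] for c in chains]))
              for name in chains[0]["accept"]}
    samples = PosteriorSamples(spec=spec, config=config, draws=draws,
                               data=shared, accept=accept)

    if not all(np.isfinite(d).all() for d in draws.values()):
        raise FitError("non-finite posterior draws encountered")
    conv = samples.convergence_table()
    worst = conv["rhat"].max()
    if np.isfinite(worst) and worst > config.rhat_warn:
        bad = conv.loc[conv["rhat"].idxmax(), "parameter"]
        warnings.warn(
            f"split-Rhat {worst:.3f} for {bad!r} exceeds {config.rhat_warn}; "
            "consider longer chains", RuntimeWarning, stacklevel=2,
        )
    return samples


# ---------------------------------------------------------------------------
# single chain


def _pointwise(family, y, eta, r):
    mu = np.exp(np.clip(eta, -700, 700))
    if family == "poisson":
        from scipy.special import gammaln
        return y * eta - mu - gammaln(y + 1.0)
    from scipy.special import gammaln
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * (eta - np.log(r + mu)))


def _dloglik(family, y, eta_new, eta_old, r):
    """Pointwise log-likelihood difference, vectorised."""
    if family == "poisson":
        return y * (eta_new - eta_old) - (np.exp(eta_new) - np.exp(eta_old))
    mu_n, mu_o = np.exp(eta_new), np.exp(eta_old)
    return (r * (np.log(r + mu_o) - np.log(r + mu_n))
            + y * (eta_new - np.log(r + mu_n) - eta_old + np.log(r + mu_o)))


def _run_chain(spec, config, graph, shared, rng):
    y, obs, offset = shared["y"], shared["obs"], shared["offset"]
    Xs0, miss_cells, miss_y = shared["Xs"], shared["miss_cells"], \
        np.flatnonzero(~obs)
    n = y.size
    k = Xs0.shape[1]
    p = k + 1
    family = spec.family
    a_tau, b_tau = config.tau_prior
    a_r, b_r = config.r_prior

    Xs = np.where(np.isnan(Xs0), 0.0, Xs0)
    D = np.column_stack([np.ones(n), Xs])

    y_obs = y[obs]
    y_safe = np.where(obs, y, 0.0)
    beta, prop_cov = _glm_init(y_obs, D[obs], offset[obs])

    # start theta at the clipped GLM log-residuals (spatial case) so the
    # burn-in does not have to discover the residual structure from zero;
    # with an overdispersed family this also prevents the chain from
    # settling in a small-r mode where the spatial effect explains nothing
    theta = np.zeros(n)
    tau, rho = 10.0, 0.5
    if spec.spatial:
        mu_glm = np.exp(np.clip(D @ beta + offset, -30, 30))
        theta = np.where(obs, np.clip(np.log((y_safe + 0.5) / mu_glm), -3, 3), 0.0)
        theta -= theta.mean()
        tau = 1.0 / max(float(theta.var()), 0.05)
    r_nb = None
    if family == "negbinom":
        mu0 = np.exp(np.clip((D @ beta + offset + theta)[obs], -30, 30))
        phi = float(np.mean(((y_obs - mu0) ** 2 - mu0) / mu0 ** 2))
        r_nb = float(np.clip(1.0 / phi, 0.5, 1e3)) if phi > 0 else 1e3

    eta = D @ beta + offset + theta

    # spatial precomputations
    if spec.spatial:
        W = graph.W
        M = graph.M
        colors = graph.coloring
        nu = graph.car_eigvals
        Wtheta = np.zeros(n)
        sum_m = float(M.sum())
        obs_f = obs.astype(float)

    # imputation state
    do_mcar = spec.imputation == "mcar" and len(miss_cells) > 0
    do_linreg = spec.imputation == "linreg" and len(miss_cells) > 0
    if do_mcar:
        Ws = graph.W_scaled
        lam_s = graph.scaled_eigvals
        alpha_c = np.zeros(k)
        Lambda = np.eye(k)
        rho_c = 0.5
        blocks = []  # (unit, covariate idx, neighbour idx, neighbour weights)
        for i in np.unique(miss_cells[:, 0]):
            mk = miss_cells[miss_cells[:, 0] == i, 1]
            row = Ws.getrow(int(i))
            blocks.append((int(i), mk, row.indices.copy(), row.data.copy()))
        ws_sum = float(Ws.sum())
    if do_linreg:
        partial = np.unique(miss_cells[:, 1])
        full_cols = np.setdiff1d(np.arange(k), partial)
        F = np.column_stack([np.ones(n)] + [Xs[:, j] for j in full_cols])
        if np.linalg.matrix_rank(F) < F.shape[1]:
            raise FitError("rank-deficient fully-observed design for linreg imputation")
        FtF = F.T @ F
        p_imp = F.shape[1]
        beta_imp = {}
        tau_c = {}
        for j in partial:
            o = ~np.isnan(Xs0[:, j])
            bj, *_ = np.linalg.lstsq(F[o], Xs0[o, j], rcond=None)
            beta_imp[int(j)] = bj
            tau_c[int(j)] = 1.0
        rows_by_cov = {int(j): miss_cells[miss_cells[:, 1] == j, 0]
                       for j in partial}

    # adaptation state
    L_prop = np.linalg.cholesky(prop_cov + 1e-10 * np.eye(p))
    log_s_beta = np.log(2.38 / np.sqrt(p))
    beta_bar = beta.copy()
    beta_cov = prop_cov.copy()
    log_s_theta = np.full(n, np.log(0.5))
    log_s_swap, log_s_rho, log_s_rhoc, log_s_r = np.log(0.5), 0.0, 0.0, np.log(0.3)
    log_s_trans = np.log(1.0)

    n_store = config.n_store
    store = {
        "beta": np.empty((n_store, p)),
        "loglik": np.empty((n_store, int(obs.sum()))),
    }
    if spec.spatial:
        store["tau"] = np.empty(n_store)
        store["rho"] = np.empty(n_store)
        if config.store_theta:
            store["theta"] = np.empty((n_store, n))
    if family == "negbinom":
        store["r"] = np.empty(n_store)
    if len(miss_cells):
        store["x_cells"] = np.empty((n_store, len(miss_cells)))
    if do_mcar:
        store["rho_c"] = np.empty(n_store)
        store["alpha_c"] = np.empty((n_store, k))
        store["Lambda_diag"] = np.empty((n_store, k))
    if miss_y.size:
        store["y_mis"] = np.empty((n_store, miss_y.size))
    mu_sum = np.zeros(n)
    theta_sum = np.zeros(n)

    acc = {name: [0, 0] for name in
           ("beta", "theta", "trans", "swap", "rho", "rho_c", "r", "impute")}

    def bump(name, hit, tries=1):
        acc[name][0] += hit
        acc[name][1] += tries

    s_idx = 0
    for it in range(config.n_iter):
        adapting = it < config.n_burnin
        g_t = 1.0 / (1.0 + it) ** 0.6

        # ---- beta block -------------------------------------------------
        step = np.exp(log_s_beta) * (L_prop @ rng.standard_normal(p))
        beta_prop = beta + step
        eta_prop = eta + D @ step
        dll = float(np.sum(_dloglik(family, y_obs, eta_prop[obs], eta[obs], r_nb)))
        dpr = -0.5 * (beta_prop @ beta_prop - beta @ beta) / config.beta_prior_sd ** 2
        a = dll + dpr
        accept = np.log(rng.random()) < a
        if accept:
            beta, eta = beta_prop, eta_prop
        bump("beta", int(accept))
        if adapting:
            log_s_beta += g_t * (min(1.0, np.exp(min(a, 0.0))) - 0.234)
            dbeta = beta - beta_bar
            beta_bar = beta_bar + g_t * dbeta
            beta_cov = beta_cov + g_t * (np.outer(dbeta, dbeta) - beta_cov)
            if it % 50 == 49:
                L_prop = np.linalg.cholesky(beta_cov + 1e-10 * np.eye(p))

        if spec.spatial:
            # ---- likelihood-invariant translation -----------------------
            # beta* = beta + d, theta* = theta - D d leaves eta unchanged;
            # the CAR prior on theta decides.  This decorrelates smooth
            # covariate fields from the spatial effect.
            d = np.exp(log_s_trans) * (L_prop @ rng.standard_normal(p))
            Dd = D @ d
            Qth = M * theta - rho * (W @ theta)
            QDd = M * Dd - rho * (W @ Dd)
            a = (-0.5 * tau * (float(Dd @ QDd) - 2.0 * float(Dd @ Qth))
                 - 0.5 * (2.0 * float(beta @ d) + float(d @ d))
                 / config.beta_prior_sd ** 2)
            accept = np.log(rng.random()) < a
            if accept:
                beta = beta + d
                theta = theta - Dd
            bump("trans", int(accept))
            if adapting:
                log_s_trans += g_t * (min(1.0, np.exp(min(a, 0.0))) - 0.234)

            Wtheta = W @ theta

            # ---- intercept/level swap (identifiability move) ------------
            delta = np.exp(log_s_swap) * rng.standard_normal()
            q1 = float(M @ theta) - rho * float(Wtheta.sum())
            c11 = (1.0 - rho) * sum_m
            a = (-0.5 * tau * (delta ** 2 * c11 - 2.0 * delta * q1)
                 - 0.5 * ((beta[0] + delta) ** 2 - beta[0] ** 2)
                 / config.beta_prior_sd ** 2)
            accept = np.log(rng.random()) < a
            if accept:
                beta = beta.copy()
                beta[0] += delta
                theta = theta - delta
                Wtheta = Wtheta - delta * M
            bump("swap", int(accept))
            if adapting:
                log_s_swap += g_t * (min(1.0, np.exp(min(a, 0.0))) - 0.44)

            # ---- theta, one colour class at a time ----------------------
            for idx in colors:
                Wt = (W @ theta)[idx]
                cond_mean = rho * Wt / M[idx]
                prec = tau * M[idx]
                dth = np.exp(log_s_theta[idx]) * rng.standard_normal(idx.size)
                th_new = theta[idx] + dth
                dlp = -0.5 * prec * ((th_new - cond_mean) ** 2
                                     - (theta[idx] - cond_mean) ** 2)
                e_old = eta[idx]
                e_new = e_old + dth
                dll = np.where(obs[idx],
                               _dloglik(family, y_safe[idx], e_new, e_old, r_nb),
                               0.0)
                a_vec = dlp + dll
                accepted = np.log(rng.random(idx.size)) < a_vec
                theta[idx] = np.where(accepted, th_new, theta[idx])
                eta[idx] = np.where(accepted, e_new, e_old)
                bump("theta", int(accepted.sum()), idx.size)
                if adapting:
                    pr = np.minimum(1.0, np.exp(np.minimum(a_vec, 0.0)))
                    log_s_theta[idx] += g_t * (pr - 0.44)

            Wtheta = W @ theta
            th_M_th = float(M @ (theta ** 2))
            th_W_th = float(theta @ Wtheta)

            # ---- tau (conjugate gamma) ----------------------------------
            quad = th_M_th - rho * th_W_th
            tau = rng.gamma(a_tau + 0.5 * n, 1.0 / (b_tau + 0.5 * max(quad, 1e-12)))

            # ---- rho (logit-scale Metropolis) ---------------------------
            z_now = np.log(rho / (1.0 - rho))
            z_new = z_now + np.exp(log_s_rho) * rng.standard_normal()
            rho_new = 1.0 / (1.0 + np.exp(-z_new))

            def rho_logpost(rr):
                return (0.5 * float(np.log1p(-rr * nu).sum())
                        - 0.5 * tau * (th_M_th - rr * th_W_th)
                        + np.log(rr) + np.log1p(-rr))

            a = rho_logpost(rho_new) - rho_logpost(rho)
            accept = np.isfinite(a) and np.log(rng.random()) < a
            if accept:
                rho = rho_new
            bump("rho", int(accept))
            if adapting:
                pr = min(1.0, np.exp(min(a, 0.0))) if np.isfinite(a) else 0.0
                log_s_rho += g_t * (pr - 0.44)

            # sum-to-zero recentring guard near the intrinsic limit
            if rho > config.center_threshold:
                shift = theta.mean()
                theta = theta - shift
                beta = beta.copy()
                beta[0] += shift
                eta = D @ beta + offset + theta

        # ---- r (NB scale, log-scale Metropolis) -------------------------
        if family == "negbinom":
            lr_new = np.log(r_nb) + np.exp(log_s_r) * rng.standard_normal()
            r_new = float(np.exp(lr_new))
            ll_new = float(np.sum(_pointwise(family, y_obs, eta[obs], r_new)))
            ll_old = float(np.sum(_pointwise(family, y_obs, eta[obs], r_nb)))
            a = (ll_new - ll_old
                 + a_r * (np.log(r_new) - np.log(r_nb)) - b_r * (r_new - r_nb))
            accept = np.log(rng.random()) < a
            if accept:
                r_nb = r_new
            bump("r", int(accept))
            if adapting:
                log_s_r += g_t * (min(1.0, np.exp(min(a, 0.0))) - 0.44)

        # ---- missing covariate cells ------------------------------------
        if do_mcar:
            Zc = Xs - alpha_c[None, :]
            H = (Zc - rho_c * (Ws @ Zc)) @ Lambda  # (Q z~) reshaped N x K
            for (i, mk, nbr, nbr_w) in blocks:
                if mk.size == 1:  # scalar fast path (the common case)
                    kk = mk[0]
                    pr_ = Lambda[kk, kk]
                    m_c = Zc[i, kk] - H[i, kk] / pr_
                    dx1 = m_c + rng.standard_normal() / np.sqrt(pr_) - Zc[i, kk]
                    dx = None
                    d_eta = beta[1 + kk] * dx1
                else:
                    P = Lambda[np.ix_(mk, mk)]  # R_ii = 1 (zero diagonal W_s)
                    Pinv = np.linalg.inv(P)
                    m_c = Zc[i, mk] - Pinv @ H[i, mk]
                    Lc = np.linalg.cholesky(Pinv)
                    dx = m_c + Lc @ rng.standard_normal(mk.size) - Zc[i, mk]
                    d_eta = float(beta[1 + mk] @ dx)
                if obs[i]:
                    a = float(_dloglik(family, y[i], eta[i] + d_eta, eta[i], r_nb))
                    accept = np.log(rng.random()) < a
                else:
                    accept = True
                bump("impute", int(accept))
                if accept:
                    if dx is None:
                        Zc[i, kk] += dx1
                        Xs[i, kk] += dx1
                        D[i, 1 + kk] += dx1
                        lam_d = Lambda[:, kk] * dx1
                    else:
                        Zc[i, mk] += dx
                        Xs[i, mk] += dx
                        D[i, 1 + mk] += dx
                        lam_d = Lambda[:, mk] @ dx
                    eta[i] += d_eta
                    H[i] += lam_d
                    H[nbr] -= rho_c * nbr_w[:, None] * lam_d[None, :]

            # alpha_c | rest (conjugate normal)
            c_r = n - rho_c * ws_sum
            u = np.ones(n) @ (Xs - rho_c * (Ws @ Xs))
            A = c_r * Lambda + config.alpha_prior_prec * np.eye(k)
            bvec = Lambda @ u
            Ainv = np.linalg.inv(A)
            mean_a = Ainv @ bvec
            alpha_c = mean_a + np.linalg.cholesky(
                0.5 * (Ainv + Ainv.T) + 1e-12 * np.eye(k)
            ) @ rng.standard_normal(k)

            # Lambda | rest (conjugate Wishart)
            Zc = Xs - alpha_c[None, :]
            RZ = Zc - rho_c * (Ws @ Zc)
            S = Zc.T @ RZ
            S = 0.5 * (S + S.T)
            scale = np.linalg.inv(np.eye(k) + S)
            scale = 0.5 * (scale + scale.T)
            Lambda = wishart.rvs(df=k + 1 + n, scale=scale, random_state=rng)
            Lambda = np.atleast_2d(Lambda)
            Lambda = 0.5 * (Lambda + Lambda.T)

            # rho_c | rest (logit-scale Metropolis)
            A0 = float(np.einsum("ij,ij->", Zc @ Lambda, Zc))
            A1 = float(np.einsum("ij,ij->", Zc @ Lambda, Ws @ Zc))

            def rhoc_logpost(rr):
                return (0.5 * k * float(np.log1p(-rr * lam_s).sum())
                        - 0.5 * (A0 - rr * A1) + np.log(rr) + np.log1p(-rr))

            z_now = np.log(rho_c / (1.0 - rho_c))
            z_new = z_now + np.exp(log_s_rhoc) * rng.standard_normal()
            rc_new = 1.0 / (1.0 + np.exp(-z_new))
            a = rhoc_logpost(rc_new) - rhoc_logpost(rho_c)
            accept = np.isfinite(a) and np.log(rng.random()) < a
            if accept:
                rho_c = rc_new
            bump("rho_c", int(accept))
            if adapting:
                pr = min(1.0, np.exp(min(a, 0.0))) if np.isfinite(a) else 0.0
                log_s_rhoc += g_t * (pr - 0.44)

        if do_linreg:
            for j, rows in rows_by_cov.items():
                bj, tc = beta_imp[j], tau_c[j]
                mu_j = F[rows] @ bj
                props = mu_j + rng.standard_normal(rows.size) / np.sqrt(tc)
                for i, xprop in zip(rows, props):
                    dx = xprop - Xs[i, j]
                    d_eta = beta[1 + j] * dx
                    if obs[i]:
                        a = float(_dloglik(family, y[i], eta[i] + d_eta,
                                           eta[i], r_nb))
                        accept = np.log(rng.random()) < a
                    else:
                        accept = True
                    bump("impute", int(accept))
                    if accept:
                        Xs[i, j] += dx
                        D[i, 1 + j] += dx
                        eta[i] += d_eta
                # beta_imp | rest
                A = tau_c[j] * FtF + 1e-8 * np.eye(p_imp)
                bvec = tau_c[j] * (F.T @ Xs[:, j])
                Ainv = np.linalg.inv(A)
                beta_imp[j] = Ainv @ bvec + np.linalg.cholesky(
                    0.5 * (Ainv + Ainv.T) + 1e-12 * np.eye(p_imp)
                ) @ rng.standard_normal(p_imp)
                # tau_c | rest
                resid = Xs[:, j] - F @ beta_imp[j]
                tau_c[j] = rng.gamma(a_tau + 0.5 * n,
                                     1.0 / (b_tau + 0.5 * float(resid @ resid)))

        # ---- missing responses (posterior predictive) -------------------
        if miss_y.size:
            mu_mis = np.exp(np.clip(eta[miss_y], -700, 30))
            if family == "poisson":
                y_draw = rng.poisson(mu_mis)
            else:
                y_draw = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_mis))

        # ---- storage ----------------------------------------------------
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            store["beta"][s_idx] = beta
            ll = _pointwise(family, y_obs, eta[obs], r_nb)
            store["loglik"][s_idx] = ll
            if spec.spatial:
                store["tau"][s_idx] = tau
                store["rho"][s_idx] = rho
                if config.store_theta:
                    store["theta"][s_idx] = theta
            if family == "negbinom":
                store["r"][s_idx] = r_nb
            if len(miss_cells):
                store["x_cells"][s_idx] = Xs[miss_cells[:, 0], miss_cells[:, 1]]
            if do_mcar:
                store["rho_c"][s_idx] = rho_c
                store["alpha_c"][s_idx] = alpha_c
                store["Lambda_diag"][s_idx] = np.diag(Lambda)
            if miss_y.size:
                store["y_mis"][s_idx] = y_draw
            mu_sum += np.exp(np.clip(eta, -700, 700))
            theta_sum += theta
            s_idx += 1

    if not np.isfinite(store["beta"]).all():
        raise FitError("divergence: non-finite regression coefficients")
    rates = {name: (h / t if t else np.nan) for name, (h, t) in acc.items()}
    return {"draws": store, "mu_sum": mu_sum, "theta_sum": theta_sum,
            "accept": rates}
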