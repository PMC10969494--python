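"""Gaussian Markov random field machinery for covariate imputation.

A spatially correlated covariate is modelled as a latent proper-CAR field
``z ~ N(alpha * 1, [tau_c (I - rho W_s)]^{-1})`` where ``W_s`` is the
adjacency scaled by its largest eigenvalue so that rho in (0, 1) guarantees a
positive-definite precision.  Missing entries are imputed from the exact
Gaussian conditional of this joint.  Several covariates are handled jointly
by a separable multivariate CAR whose precision is the Kronecker product
``Lambda (x) (I - rho W_s)`` with ``Lambda`` a K x K between-covariate
precision.  For nonspatial model variants the imputation falls back to an
ordinary Bayesian linear regression of the partially observed covariate on
the fully observed ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class Gaussian(NamedTuple):
    """A (small, dense) multivariate normal returned by conditioning."""

    mean: np.ndarray
    cov: np.ndarray

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        L = np.linalg.cholesky(self.cov + 1e-12 * np.eye(len(self.mean)))
        if size is None:
            return self.mean + L @ rng.standard_normal(len(self.mean))
        return self.mean + rng.standard_normal((size, len(self.mean))) @ L.T


def _as_csr(W) -> sp.csr_matrix:
    return W.W_scaled if hasattr(W, "W_scaled") else sp.csr_matrix(W, dtype=float)


@dataclass
class ProperCARModel:
    """Proper-CAR field with mean alpha and precision tau_c (I - rho W_s)."""

    alpha: float
    rho: float
    tau_c: float
    W_scaled: sp.csr_matrix

    def __post_init__(self):
        self.W_scaled = _as_csr(self.W_scaled)
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho={self.rho} must lie in (0, 1)")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")

    @property
    def n(self) -> int:
        return self.W_scaled.shape[0]

    def precision(self) -> sp.csr_matrix:
        return (self.tau_c * (sp.identity(self.n) - self.rho * self.W_scaled)).tocsr()


@dataclass
class MCARModel:
    """Separable multivariate CAR: precision Lambda (x) (I - rho W_s).

    ``Lambda`` couples the K covariate fields at a site; a single shared rho
    governs the spatial decay of every field.
    """

    alphas: np.ndarray
    rho: float
    Lambda: np.ndarray
    W_scaled: sp.csr_matrix

    def __post_init__(self):
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        self.W_scaled = _as_csr(self.W_scaled)
        k = self.alphas.size
        if self.Lambda.shape != (k, k):
            raise ValueError("Lambda must be K x K with K = len(alphas)")
        if not np.allclose(self.Lambda, self.Lambda.T):
            raise ValueError("Lambda must be symmetric")
        if np.linalg.eigvalsh(self.Lambda).min() <= 0:
            raise ValueError("Lambda must be positive definite")
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho={self.rho} must lie in (0, 1)")

    @property
    def k(self) -> int:
        return self.alphas.size

    @property
    def n(self) -> int:
        return self.W_scaled.shape[0]


@dataclass
class LinRegImputationModel:
    """x = X beta + eps, eps ~ N(0, 1/tau_c): nonspatial imputation model."""

    beta: np.ndarray
    tau_c: float

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")


# ---------------------------------------------------------------------------
# densities


def _sparse_logdet(Q: sp.spmatrix) -> float:
    """log det of a sparse SPD matrix via LU (U-diagonal product)."""
    lu = splu(Q.tocsc())
    diag = lu.U.diagonal()
    if (diag <= 0).any():
        # permutation sign bookkeeping: SPD matrices have positive det, so a
        # negative product only reflects row/column permutation parity
        return float(np.log(np.abs(diag)).sum())
    return float(np.log(diag).sum())


def car_logpdf(values, model: ProperCARModel) -> float:
    """Exact log density of a proper-CAR field via sparse factorization."""
    x = np.asarray(values, dtype=float)
    if x.shape != (model.n,):
        raise ValueError("values length must equal the node count")
    Q = model.precision()
    r = x - model.alpha
    quad = float(r @ (Q @ r))
    logdet = _sparse_logdet(Q)
    if not np.isfinite(logdet):
        raise ValueError("precision matrix is not positive definite")
    return 0.5 * (logdet - model.n * np.log(2.0 * np.pi) - quad)


# ---------------------------------------------------------------------------
# exact conditionals


def conditional_missing(x_obs, miss_idx, model: ProperCARModel) -> Gaussian:
    """Gaussian conditional of the missing entries given the observed ones.

    ``x_obs`` is the full-length field with arbitrary (ignored) entries at
    ``miss_idx``.  With joint precision tau_c (I - rho W_s) partitioned into
    missing (m) and observed (o) blocks, the conditional is

        mean = alpha + (I_mm - rho W_mm)^{-1} rho W_mo (x_o - alpha)
        cov  = [tau_c (I_mm - rho W_mm)]^{-1}
    """
    x = np.asarray(x_obs, dtype=float)
    if x.shape != (model.n,):
        raise ValueError("x_obs must be the full-length field")
    miss = np.asarray(miss_idx, dtype=int)
    if miss.size == 0:
        return Gaussian(np.empty(0), np.empty((0, 0)))
    if miss.size >= model.n:
        raise ValueError("all nodes missing: no conditioning information")
    obs = np.setdiff1d(np.arange(model.n), miss)
    Ws = model.W_scaled
    A_mm = np.eye(miss.size) - model.rho * Ws[miss][:, miss].toarray()
    W_mo = Ws[miss][:, obs].toarray()
    mean = model.alpha + np.linalg.solve(A_mm, model.rho * (W_mo @ (x[obs] - model.alpha)))
    cov = np.linalg.inv(model.tau_c * A_mm)
    cov = 0.5 * (cov + cov.T)
    return Gaussian(mean, cov)


def mcar_joint_precision(model: MCARModel, W_scaled=None) -> sp.csr_matrix:
    """Joint precision Lambda (x) (I - rho W_s) over the N*K stacked field.

    Stacking is covariate-major: cell (site i, covariate k) sits at index
    k * N + i, i.e. the K fields are concatenated column by column.
    """
    Ws = _as_csr(W_scaled) if W_scaled is not None else model.W_scaled
    R = sp.identity(Ws.shape[0]) - model.rho * Ws
    return sp.kron(sp.csr_matrix(model.Lambda), R, format="csr")


def mcar_conditional_missing(X_obs, miss_cells, model: MCARModel) -> Gaussian:
    """Conditional of missing cells under the joint MCAR precision.

    ``X_obs`` is the N x K covariate matrix (entries at missing cells are
    ignored); ``miss_cells`` is a sequence of (site, covariate) pairs, or an
    index array into the covariate-major stacked field.  Returned moments are
    ordered as given.
    """
    X = np.asarray(X_obs, dtype=float)
    n, k = model.n, model.k
    if X.shape != (n, k):
        raise ValueError("X_obs must be N x K")
    cells = np.asarray(miss_cells)
    if cells.size == 0:
        return Gaussian(np.empty(0), np.empty((0, 0)))
    if cells.ndim == 2:
        stacked = cells[:, 1].astype(int) * n + cells[:, 0].astype(int)
    else:
        stacked = cells.astype(int)
    if stacked.size >= n * k:
        raise ValueError("all cells missing: no conditioning information")
    Q = mcar_joint_precision(model)
    z = (X - model.alphas[None, :]).ravel(order="F")  # covariate-major stack
    alpha_stack = np.repeat(model.alphas, n)
    obs = np.setdiff1d(np.arange(n * k), stacked)
    Q_mm = Q[stacked][:, stacked].toarray()
    Q_mo = Q[stacked][:, obs]
    mean = alpha_stack[stacked] - np.linalg.solve(Q_mm, Q_mo @ z[obs])
    cov = np.linalg.inv(Q_mm)
    cov = 0.5 * (cov + cov.T)
    return Gaussian(mean, cov)


def linreg_imputation(X, x, model: LinRegImputationModel) -> Gaussian:
    """Conditional N(X_mis beta, (1/tau_c) I) for the missing rows of ``x``.

    ``X`` is the fully observed design (include a ones column for an
    intercept); missing rows of ``x`` are its NaN entries.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x = np.asarray(x, dtype=float)
    if X.shape[0] != x.size:
        raise ValueError("X rows must match length of x")
    if X.shape[1] != model.beta.size:
        raise ValueError("design width must match coefficient vector")
    mis = np.isnan(x)
    obs_rows = X[~mis]
    if obs_rows.shape[0] >= model.beta.size and \
            np.linalg.matrix_rank(obs_rows) < X.shape[1]:
        raise ValueError("rank-deficient design over observed rows")
    mean = X[mis] @ model.beta
    cov = np.eye(int(mis.sum())) / model.tau_c
    return Gaussian(mean, cov)


def fit_linreg_imputation(X, x, *, tau_prior=(1.0, 5e-5)) -> LinRegImputationModel:
    """Point fit (OLS + moment estimate of tau_c) of the linear imputation
    model over the observed rows; the full-Bayes treatment (priors on beta
    and tau_c) lives in the sampler."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    Xo, xo = X[obs], x[obs]
    if Xo.shape[0] < X.shape[1]:
        raise ValueError("fewer observed rows than coefficients")
    if np.linalg.matrix_rank(Xo) < X.shape[1]:
        raise ValueError("rank-deficient design over observed rows")
    beta, *_ = np.linalg.lstsq(Xo, xo, rcond=None)
    resid = xo - Xo @ beta
    dof = max(Xo.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    return LinRegImputationModel(beta=beta, tau_c=1.0 / max(sigma2, 1e-12))
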