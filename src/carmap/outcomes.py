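"""Poisson and negative-binomial observation models with log offsets.

Counts in areal unit *i* follow either

    y_i ~ Poisson(mu_i)            or     y_i ~ NB(r, mu_i)

with log mu_i = x_i' beta + O_i + theta_i, offset O_i = log(N_i), and theta_i
an optional CAR spatial effect.  The NB is parameterized by (r, mean mu):
Var(y) = mu (1 + mu / r), equivalently a standard NB draw with size r and
success probability p = r / (r + mu); r -> infinity recovers the Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y != np.round(y)) | ~np.isfinite(y)).any():
        raise ValueError("counts must be nonnegative integers")
    return y


def linear_predictor(x, beta, offset, theta=0.0) -> np.ndarray:
    """eta_i = x_i' beta + O_i + theta_i (model mean is exp(eta_i))."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing covariate entries: impute before the linear predictor")
    if x.shape[1] != beta.size:
        raise ValueError("covariate and coefficient dimensions disagree")
    eta = x @ beta + np.asarray(offset, dtype=float) + np.asarray(theta, dtype=float)
    if np.any(eta > 700):
        raise OverflowError(
            "linear predictor overflows exp(); rescale covariates or coefficients"
        )
    return eta


def poisson_logpmf(y, mu) -> np.ndarray:
    """Pointwise Poisson log pmf: y log mu - mu - log(y!)."""
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if (mu <= 0).any():
        raise ValueError("Poisson means must be positive")
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def poisson_loglik(y, mu) -> float:
    return float(np.sum(poisson_logpmf(y, mu)))


def negbinom_logpmf(y, mu, r) -> np.ndarray:
    """Pointwise NB log pmf with size r and success probability r/(r+mu)."""
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if r <= 0:
        raise ValueError("NB scale r must be positive")
    if (mu <= 0).any():
        raise ValueError("NB means must be positive")
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    )


def negbinom_loglik(y, mu, r) -> float:
    return float(np.sum(negbinom_logpmf(y, mu, r)))


def family_logpmf(family: str, y, mu, r=None) -> np.ndarray:
    if family == "poisson":
        return poisson_logpmf(y, mu)
    if family == "negbinom":
        return negbinom_logpmf(y, mu, r)
    raise ValueError(f"unknown family {family!r}")


def overdispersion_index(y) -> float:
    """Sample variance over sample mean of the non-missing counts.

    Uses the unbiased (n - 1) variance.  Values well above 1 indicate more
    variability than a Poisson model can carry; a ratio above ~2 is the usual
    trigger for a negative-binomial (or spatial random effect) treatment.
    """
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 2:
        raise ValueError("need at least two observed counts")
    mean = y.mean()
    if mean <= 0:
        raise ValueError("mean of observed counts must be positive")
    return float(y.var(ddof=1) / mean)
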