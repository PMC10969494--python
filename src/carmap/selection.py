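"""Bayesian model-comparison criteria for fitted models.

DIC  = -2 log p(y | theta_hat) + 2 p_DIC,
       p_DIC = 2 [ log p(y | theta_hat) - mean_s log p(y | theta_s) ],
       theta_hat = posterior mean of every parameter entering the likelihood
       (regression coefficients, spatial effects, NB scale, imputed
       covariates);
WAIC = -2 lppd + 2 p_WAIC,
       lppd  = sum_i log( mean_s p(y_i | theta_s) ),
       p_WAIC = sum_i var_s log p(y_i | theta_s);
RMSE / RSE compare observed counts with posterior-mean fitted counts, RSE
being the squared error relative to the mean-only predictor
(sum (y - yhat)^2 / sum (y - ybar)^2, so a mean predictor scores 1).

DIC differences are annotated with the usual qualitative reading: more than
10 units is an important difference, 3-10 substantial, below 3 negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorSamples

__all__ = ["dic", "waic", "rmse_rse", "ComparisonRecord", "evaluate",
           "compare_models", "dic_gap_label"]


def dic(samples: PosteriorSamples) -> tuple[float, float]:
    """Deviance information criterion: returns (DIC, p_DIC)."""
    ll = samples.loglik_pointwise
    if ll.size == 0:
        raise ValueError("no stored log-likelihood draws")
    mean_ll = float(ll.sum(axis=1).mean())
    ll_hat = float(samples.loglik_at_posterior_mean().sum())
    p_dic = 2.0 * (ll_hat - mean_ll)
    return -2.0 * ll_hat + 2.0 * p_dic, p_dic


def waic(samples: PosteriorSamples) -> tuple[float, float, float]:
    """Widely applicable information criterion: (WAIC, p_WAIC, lppd)."""
    ll = samples.loglik_pointwise
    s = ll.shape[0]
    if s == 0:
        raise ValueError("no stored log-likelihood draws")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    if s == 1:
        warnings.warn("single draw: p_WAIC treated as 0", RuntimeWarning,
                      stacklevel=2)
        p_waic = 0.0
    else:
        p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * lppd + 2.0 * p_waic, p_waic, lppd


def rmse_rse(observed, fitted) -> tuple[float, float]:
    """Root mean squared error and relative squared error of fitted counts."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if y.shape != f.shape:
        raise ValueError("observed and fitted lengths differ")
    err = y - f
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if y.size < 2:
        raise ValueError("RSE needs at least two observations")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("constant observed vector: RSE undefined")
    return rmse, float(np.sum(err ** 2) / denom)


@dataclass
class ComparisonRecord:
    """One row of the cross-model comparison table."""

    label: str
    dic: float
    waic: float
    rmse: float
    rse: float
    p_dic: float
    p_waic: float

    def __post_init__(self):
        vals = [self.dic, self.waic, self.rmse, self.rse]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("comparison criteria must be finite")
        if self.rmse < 0 or self.rse < 0:
            raise ValueError("RMSE and RSE must be nonnegative")


def evaluate(samples: PosteriorSamples, label: str | None = None) -> ComparisonRecord:
    """Compute all four criteria for one fitted model."""
    d, p_d = dic(samples)
    w, p_w, _ = waic(samples)
    obs = samples.data["obs"]
    rmse, rse = rmse_rse(samples.data["y"][obs], samples.fitted_mean[obs])
    return ComparisonRecord(
        label=label if label is not None else samples.spec.label,
        dic=d, waic=w, rmse=rmse, rse=rse, p_dic=p_d, p_waic=p_w,
    )


def dic_gap_label(gap: float) -> str:
    gap = abs(gap)
    if gap > 10:
        return "important"
    if gap >= 3:
        return "substantial"
    return "negligible"


def compare_models(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Rank models by DIC and annotate each gap to the best model."""
    if len(records) < 2:
        raise ValueError("need at least two models to compare")
    df = pd.DataFrame([{
        "model": r.label, "DIC": r.dic, "WAIC": r.waic,
        "RMSE": r.rmse, "RSE": r.rse, "p_DIC": r.p_dic, "p_WAIC": r.p_waic,
    } for r in records]).sort_values("DIC", kind="stable").reset_index(drop=True)
    best = df["DIC"].iloc[0]
    df["dic_gap_to_best"] = df["DIC"] - best
    df["verdict"] = df["dic_gap_to_best"].map(dic_gap_label)
    df.loc[0, "verdict"] = "best"
    return df
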