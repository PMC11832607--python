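"""Cause-specific Cox analysis models and Rubin's-rules pooling.

The analysis model of a cause ``k`` treats events of the other causes as
censoring at their occurrence time and regresses the cause-specific
hazard on the 10 covariates.  Estimates from M completed datasets are
combined with Rubin's rules; confidence intervals use t quantiles with
the Barnard-Rubin small-sample degrees of freedom, taking the
complete-data degrees of freedom as ``n - 10`` (records minus
covariates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxError, fit_cox
from .mice import ImputedStack
from .population import COVARIATE_NAMES

__all__ = [
    "FitResult",
    "PooledEstimate",
    "fit_cause_specific",
    "pool_rubin",
    "complete_case",
    "pool_stack",
    "single_fit_table",
]


@dataclass(frozen=True)
class FitResult:
    """One cause-specific Cox fit: point estimates and model SEs."""

    cause: int
    beta_hat: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.beta_hat)):
            raise ValueError("invalid fit: SEs must be positive and "
                             "estimates finite")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules summary for one coefficient."""

    qbar: float
    ubar: float
    b: float
    t_var: float
    df: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t_var))


def fit_cause_specific(data: pd.DataFrame, cause: int) -> FitResult:
    """Fit the cause-``k`` Cox model on complete data (Efron ties)."""
    if cause not in (1, 2, 3):
        raise ValueError("cause must be 1, 2 or 3")
    covs = data[list(COVARIATE_NAMES)]
    if covs.isna().any().any():
        raise ValueError("fit_cause_specific requires complete covariates")
    fit = fit_cox(covs.to_numpy(dtype=float), data["time"].to_numpy(),
                  (data["event"].to_numpy() == cause).astype(float),
                  names=COVARIATE_NAMES)
    return FitResult(cause=cause, beta_hat=fit.beta, se=fit.se)


def pool_rubin(estimates, variances, nu_com: float) -> PooledEstimate:
    """Rubin's rules with Barnard-Rubin degrees of freedom.

    ``qbar`` = mean estimate, ``ubar`` = mean within variance, ``b`` =
    between-imputation sample variance, total variance
    ``T = ubar + (1 + 1/M) b``.  With missing-information fraction
    ``lam = (1 + 1/M) b / T`` the degrees of freedom combine
    ``nu_old = (M - 1) / lam^2`` and
    ``nu_obs = ((nu_com + 1)/(nu_com + 3)) nu_com (1 - lam)``
    harmonically; ``b = 0`` is the no-missing-information limit
    ``df = ((nu_com + 1)/(nu_com + 3)) nu_com``.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    if np.any(u <= 0):
        raise ValueError("within-imputation variances must be positive")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    if b <= 1e-12 * (ubar + qbar ** 2):   # numerically identical estimates
        b = 0.0
    t_var = ubar + (1.0 + 1.0 / m) * b
    obs_factor = (nu_com + 1.0) / (nu_com + 3.0) * nu_com
    if b == 0:
        df = obs_factor
    else:
        lam = (1.0 + 1.0 / m) * b / t_var
        nu_old = (m - 1.0) / lam ** 2
        nu_obs = obs_factor * (1.0 - lam)
        df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    half = stats.t.ppf(0.975, df) * np.sqrt(t_var)
    return PooledEstimate(qbar=qbar, ubar=ubar, b=b, t_var=t_var, df=df,
                          ci_low=qbar - half, ci_high=qbar + half)


def complete_case(data: pd.DataFrame):
    """Drop records with any missing covariate and fit all three models."""
    covs = data[list(COVARIATE_NAMES)]
    keep = ~covs.isna().any(axis=1)
    sub = data.loc[keep]
    if len(sub) < len(COVARIATE_NAMES) + 2:
        raise ValueError(
            f"only {len(sub)} complete records; too few to fit 10 covariates")
    return tuple(fit_cause_specific(sub, k) for k in (1, 2, 3))


def pool_stack(stack: ImputedStack, nu_com: float | None = None) -> pd.DataFrame:
    """Fit the 3 analysis models in each completed dataset and pool.

    Returns a tidy frame with one row per (cause, variable):
    ``qbar, se, df, ci_low, ci_high, b, ubar``.
    """
    n = len(stack.datasets[0])
    nu_com = nu_com if nu_com is not None else n - len(COVARIATE_NAMES)
    fits = {k: [] for k in (1, 2, 3)}
    for d in stack.datasets:
        for k in (1, 2, 3):
            fits[k].append(fit_cause_specific(d, k))
    rows = []
    for k in (1, 2, 3):
        est = np.vstack([f.beta_hat for f in fits[k]])
        var = np.vstack([f.se ** 2 for f in fits[k]])
        for j, name in enumerate(COVARIATE_NAMES):
            p = pool_rubin(est[:, j], var[:, j], nu_com)
            rows.append({"cause": k, "variable": name, "qbar": p.qbar,
                         "se": p.se, "df": p.df, "ci_low": p.ci_low,
                         "ci_high": p.ci_high, "b": p.b, "ubar": p.ubar})
    return pd.DataFrame(rows)


def single_fit_table(fit_results, n: int) -> pd.DataFrame:
    """Tidy table for a non-imputation arm (complete-case / no-missing).

    Wald intervals with t quantiles at ``n - 10`` degrees of freedom.
    """
    df_t = n - len(COVARIATE_NAMES)
    tq = stats.t.ppf(0.975, df_t)
    rows = []
    for f in fit_results:
        for j, name in enumerate(COVARIATE_NAMES):
            rows.append({"cause": f.cause, "variable": name,
                         "qbar": f.beta_hat[j], "se": f.se[j], "df": df_t,
                         "ci_low": f.beta_hat[j] - tq * f.se[j],
                         "ci_high": f.beta_hat[j] + tq * f.se[j],
                         "b": 0.0, "ubar": f.se[j] ** 2})
    return pd.DataFrame(rows)
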