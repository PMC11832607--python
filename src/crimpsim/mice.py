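"""Chained-equations imputation with predictive mean matching.

Each incomplete covariate is imputed by Bayesian-linear-regression
predictive mean matching (PMM, type-1 matching): regression parameters
are drawn from their posterior (scaled inverse-chi-square residual
variance, normal coefficients), predicted means are computed with the
point estimates for observed rows and the drawn parameters for missing
rows, and each missing cell receives the observed value of one of the
``k`` donors with nearest predicted mean.  Because donors are observed
values, binary variables are imputed in {0, 1} and continuous
imputations stay within the observed range without any per-type model
switching.

The predictor set for every target combines the nine other covariates
with outcome-derived features (cause-specific cumulative hazards, event
indicators and their interactions, see :mod:`crimpsim.hazards`);
interaction columns are passively recomputed from current imputed values
at every cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazards import build_imputation_predictors, compute_hazard_features
from .population import AMPUTABLE_NAMES

__all__ = ["ImputedStack", "pmm_impute_variable", "mice", "bayes_linear_draw"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputedStack:
    """M completed copies of a dataset plus provenance."""

    datasets: tuple
    strategy: str
    iterations: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)


def _drop_aliased(Z: np.ndarray):
    """Indices of a maximal linearly independent column subset (QR with
    column pivoting); logs when columns are dropped."""
    from scipy.linalg import qr

    _, R, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < Z.shape[1]:
        log.warning("dropping %d aliased predictor column(s)", Z.shape[1] - rank)
    return keep


def bayes_linear_draw(Z: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw for a normal linear model under the standard
    noninformative prior.

    Returns ``(beta_hat, beta_draw, sigma_draw, keep)`` where ``keep``
    indexes the non-aliased columns of ``Z`` actually used.
    """
    n, p = Z.shape
    keep = _drop_aliased(Z)
    Zk = Z[:, keep]
    p_eff = Zk.shape[1]
    if n < p_eff + 2:
        raise ValueError(
            f"too few observed rows ({n}) for {p_eff} predictors; "
            "need at least predictors + 2")
    beta_hat, _, _, _ = np.linalg.lstsq(Zk, y, rcond=None)
    resid = y - Zk @ beta_hat
    df = n - p_eff
    rss = float(resid @ resid)
    sigma2_draw = rss / rng.chisquare(df) if rss > 0 else 0.0
    # coefficient posterior: N(beta_hat, sigma2 (Z'Z)^-1)
    ZtZ = Zk.T @ Zk
    ZtZ += np.eye(p_eff) * (1e-12 * np.trace(ZtZ) / p_eff)  # numeric guard
    L = np.linalg.cholesky(np.linalg.inv(ZtZ))
    beta_draw = beta_hat + np.sqrt(sigma2_draw) * (L @ rng.standard_normal(p_eff))
    return beta_hat, beta_draw, np.sqrt(sigma2_draw), keep


def pmm_impute_variable(target: np.ndarray, predictors: np.ndarray,
                        donors: int = 5,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Impute missing entries of ``target`` by type-1 PMM.

    Observed rows keep their values.  For each missing row the ``donors``
    observed rows with predicted mean nearest to the missing row's
    (drawn-parameter) predicted mean form the donor pool; one donor's
    observed value is copied uniformly at random.
    """
    rng = rng if rng is not None else np.random.default_rng()
    y = np.asarray(target, dtype=float)
    miss = np.isnan(y)
    if not miss.any():
        return y.copy()
    obs = ~miss
    Z = np.column_stack([np.ones(len(y)), np.asarray(predictors, dtype=float)])
    if np.isnan(Z[obs]).any():
        raise ValueError("predictors must be complete for rows with observed target")
    beta_hat, beta_draw, _, keep = bayes_linear_draw(Z[obs], y[obs], rng)
    yhat_obs = Z[obs][:, keep] @ beta_hat          # point estimates (type 1)
    yhat_mis = Z[miss][:, keep] @ beta_draw        # drawn parameters

    order = np.argsort(yhat_obs, kind="stable")
    sorted_means = yhat_obs[order]
    y_obs_sorted = y[obs][order]
    k = min(donors, len(sorted_means))

    pos = np.searchsorted(sorted_means, yhat_mis)
    out = y.copy()
    n_obs = len(sorted_means)
    # candidate window of k neighbors on each side, then k nearest
    offs = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offs, 0, n_obs - 1)
    dist = np.abs(sorted_means[cand] - yhat_mis[:, None])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    pick = nearest[np.arange(len(yhat_mis)), rng.integers(0, k, size=len(yhat_mis))]
    donor_rows = cand[np.arange(len(yhat_mis)), pick]
    out[miss] = y_obs_sorted[donor_rows]
    return out


def _visit_order(data: pd.DataFrame) -> list[str]:
    """Amputable variables in ascending order of missingness count."""
    counts = data[AMPUTABLE_NAMES].isna().sum()
    return list(counts[counts > 0].sort_values(kind="stable").index)


def initial_fill(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Replace each missing cell by a random draw from the observed
    values of the same variable."""
    out = data.copy()
    for col in AMPUTABLE_NAMES:
        miss = out[col].isna()
        if miss.any():
            observed = out.loc[~miss, col].to_numpy()
            if len(observed) == 0:
                raise ValueError(f"variable {col!r} has no observed values")
            out.loc[miss, col] = rng.choice(observed, size=int(miss.sum()))
    return out


def mice(data: pd.DataFrame, strategy: str = "all_causes", m: int = 10,
         cycles: int = 10, donors: int = 5, seed: int = 0) -> ImputedStack:
    """Multiple imputation by chained equations with PMM.

    Runs ``m`` independent chains.  Each chain initializes missing cells
    from observed draws, then for ``cycles`` iterations visits the
    incomplete variables in fixed ascending-missingness order, imputing
    each from the strategy's predictor set built on the current completed
    data (hazard features are fixed; interactions are recomputed).
    """
    if data["time"].isna().any() or data["event"].isna().any():
        raise ValueError("time and event must be complete")
    features = compute_hazard_features(data["time"].to_numpy(),
                                       data["event"].to_numpy())
    order = _visit_order(data)
    ss = np.random.SeedSequence([seed, 811])
    completed = []
    for chain_ss in ss.spawn(m):
        rng = np.random.default_rng(chain_ss)
        current = initial_fill(data, rng)
        for _ in range(cycles if order else 0):
            for col in order:
                preds = build_imputation_predictors(current, features, col, strategy)
                y = data[col].to_numpy(dtype=float)   # original missingness mask
                filled = pmm_impute_variable(
                    np.where(np.isnan(y), np.nan, y), preds,
                    donors=donors, rng=rng)
                current[col] = filled
        completed.append(current)
    return ImputedStack(datasets=tuple(completed), strategy=strategy,
                        iterations=cycles, seed=seed)
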