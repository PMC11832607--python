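"""Vectorized Newton-Raphson fitting of the Cox proportional-hazards model.

Implements the partial likelihood with Efron's correction for tied event
times.  The score and observed information are assembled with suffix
cumulative sums and a summation-reordering identity, so each Newton step
costs O(n p^2) with only BLAS-level Python overhead; fitting the ten-
covariate models of this package takes milliseconds at n = 1,000 and a
few seconds at n = 10^6.  A cause-specific model is obtained by passing
the indicator of one event type, which treats competing events as
censoring at their occurrence time.

The fitter is cross-checked in the test suite against an independent
partial-likelihood implementation (lifelines) to 1e-6 on a fixture that
includes tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "fit_cox", "breslow_baseline", "CoxError"]


class CoxError(RuntimeError):
    """Fitting failure (separation, non-convergence, degenerate input)."""


@dataclass(frozen=True)
class CoxFit:
    """Maximum partial-likelihood estimate with model-based covariance."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_events: int
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _efron_terms(time_s, event_s):
    """Group sorted times; return per-(group, within-tie l) bookkeeping.

    Returns (group_start, group_n_events, term_group, term_frac) where the
    flattened Efron terms enumerate l = 0..d-1 for each group with d tied
    events, and term_frac = l/d.
    """
    # boundaries of distinct observed times
    new_group = np.empty(len(time_s), dtype=bool)
    new_group[0] = True
    np.not_equal(time_s[1:], time_s[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    group_start = np.flatnonzero(new_group)
    n_groups = len(group_start)
    d = np.bincount(group_id, weights=event_s.astype(float), minlength=n_groups)
    ev_groups = np.flatnonzero(d > 0)
    d_ev = d[ev_groups].astype(int)
    term_group = np.repeat(ev_groups, d_ev)
    within = np.concatenate([np.arange(k) for k in d_ev]) if len(d_ev) else np.array([], dtype=int)
    term_frac = within / np.repeat(d_ev, d_ev)
    return group_id, group_start, d, term_group, term_frac


def _loglik_score_info(X_s, event_s, eta, group_id, group_start, d,
                       term_group, term_frac, need_info=True):
    """Efron log partial likelihood, score and observed information.

    Uses suffix cumsums at group boundaries for the risk-set sums and the
    reordering  sum_e A_e * S2_e = X' diag(w * G) X  with
    G_j = sum_{groups e <= group(j)} A_e  to avoid any n x p x p tensor.
    """
    n, p = X_s.shape
    w = np.exp(eta)
    wX = X_s * w[:, None]

    # suffix sums at each group start
    S0_cum = np.cumsum(w[::-1])[::-1]
    S0_g = S0_cum[group_start]                      # (n_groups,)
    S1_cum = np.cumsum(wX[::-1], axis=0)[::-1]
    S1_g = S1_cum[group_start]                      # (n_groups, p)

    # tied-event contributions within each group
    n_groups = len(group_start)
    ev = event_s.astype(bool)
    c0 = np.bincount(group_id[ev], weights=w[ev], minlength=n_groups)
    c1 = np.zeros((n_groups, p))
    np.add.at(c1, group_id[ev], wX[ev])

    S0_el = S0_g[term_group] - term_frac * c0[term_group]
    if np.any(S0_el <= 0):
        raise CoxError("non-positive risk-set sum (numerical overflow)")
    inv_S0 = 1.0 / S0_el

    loglik = float(eta[ev].sum() - np.log(S0_el).sum())

    # per-group aggregates of the Efron terms
    A = np.bincount(term_group, weights=inv_S0, minlength=n_groups)
    B = np.bincount(term_group, weights=term_frac * inv_S0, minlength=n_groups)

    score = X_s[ev].sum(axis=0) - (A[:, None] * S1_g).sum(axis=0) \
        + (B[:, None] * c1).sum(axis=0)
    if not need_info:
        return loglik, score, None

    # sum_el S2_el / S0_el  via reordering
    G = np.cumsum(A)[group_id]                      # per-record cumulative A
    H_a = (X_s * (w * G)[:, None]).T @ X_s
    Bj = B[group_id[ev]]
    Xe = X_s[ev]
    H_b = (Xe * (w[ev] * Bj)[:, None]).T @ Xe
    # sum_el m_el m_el'
    M = (S1_g[term_group] - term_frac[:, None] * c1[term_group]) * inv_S0[:, None]
    info = H_a - H_b - M.T @ M
    return loglik, score, info


def fit_cox(X, time, event, names=None, tol: float = 1e-9,
            max_iter: int = 60) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) array
        Covariate matrix (no intercept; internally centered and scaled).
    time : (n,) array
        Positive observed times.
    event : (n,) array
        1 for an event of the cause being modeled, 0 otherwise
        (censoring or a competing event).
    names : sequence of str, optional
        Covariate names used in error messages.

    Raises
    ------
    CoxError
        On empty input, no events, constant columns, separation or
        non-convergence.
    """
    X = np.ascontiguousarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    if n == 0:
        raise CoxError("empty dataset")
    n_events = int(event.sum())
    if n_events == 0:
        raise CoxError("no events of the requested cause")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    bad = np.flatnonzero(scale == 0)
    if len(bad):
        raise CoxError(f"constant covariate column: {names[bad[0]]}")
    Xz = (X - center) / scale

    order = np.argsort(time, kind="stable")
    X_s = np.ascontiguousarray(Xz[order])
    time_s = time[order]
    event_s = np.asarray(event, dtype=float)[order]

    group_id, group_start, d, term_group, term_frac = _efron_terms(time_s, event_s)

    beta = np.zeros(p)
    eta = X_s @ beta
    ll, score, info = _loglik_score_info(
        X_s, event_s, eta, group_id, group_start, d, term_group, term_frac)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise CoxError(f"singular information matrix: {exc}") from None
        # step halving on decrease of the log likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            eta = X_s @ cand
            if np.abs(eta).max() > 200:  # guard exp overflow / separation
                factor *= 0.5
                continue
            ll_new, score_new, info_new = _loglik_score_info(
                X_s, event_s, eta, group_id, group_start, d,
                term_group, term_frac)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            raise CoxError("step halving failed to improve the likelihood")
        converged = (ll_new - ll) < tol * (abs(ll_new) + 1.0) and \
            np.abs(score_new).max() < 1e-6 * (n_events + 10.0)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if converged:
            break
    else:
        raise CoxError(f"no convergence in {max_iter} Newton iterations")

    if np.abs(beta).max() > 50:
        j = int(np.abs(beta).argmax())
        raise CoxError(
            f"monotone likelihood / separation suspected for covariate "
            f"'{names[j]}' (standardized coefficient {beta[j]:.1f})")

    cov_z = np.linalg.inv(info)
    D = 1.0 / scale
    return CoxFit(beta=beta * D, cov=cov_z * np.outer(D, D),
                  loglik=ll, n_events=n_events, n_iter=it)


def breslow_baseline(X, time, event, beta):
    """Breslow estimate of the baseline cumulative hazard at ``beta``.

    Returns ``(times, H0)``: distinct event times in increasing order and
    the cumulative hazard immediately after each.  Evaluate with
    ``H0[np.searchsorted(times, t, side='right') - 1]`` (0 before the
    first event time); see :func:`evaluate_step`.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="stable")
    time_s = time[order]
    event_s = event[order]
    w = np.exp(X[order] @ beta)
    new_group = np.empty(len(time_s), dtype=bool)
    new_group[0] = True
    np.not_equal(time_s[1:], time_s[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    group_start = np.flatnonzero(new_group)
    S0_g = np.cumsum(w[::-1])[::-1][group_start]
    d = np.bincount(group_id, weights=event_s, minlength=len(group_start))
    keep = d > 0
    times = time_s[group_start][keep]
    H0 = np.cumsum(d[keep] / S0_g[keep])
    return times, H0


def evaluate_step(times, values, t):
    """Evaluate a right-continuous step function (0 before ``times[0]``)."""
    idx = np.searchsorted(times, t, side="right")
    padded = np.concatenate([[0.0], values])
    return padded[idx]
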