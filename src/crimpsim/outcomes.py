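"""Competing-risks outcome generation and censoring calibration.

Event times follow the standard inversion construction for constant
cause-specific hazards: the all-cause hazard for subject ``i`` is
``sum_k lambda_k * exp(x_i' beta_k)``, the event time is an exponential
draw with that rate, and the event type is multinomial with
probabilities proportional to the cause-specific hazards.  Censoring is
exponential with a rate calibrated by bisection so that the realized
censored proportion hits the target (25% by default).

The "true" coefficient values of a scenario are defined operationally:
the three cause-specific Cox models fitted to the complete
super-population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import fit_cox
from .population import (
    COVARIATE_NAMES,
    CoefficientSet,
    CovariateModel,
    ScenarioConfig,
    generate_covariates,
)

__all__ = [
    "TrueValues",
    "simulate_event",
    "simulate_events",
    "calibrate_censoring",
    "apply_censoring",
    "build_superpopulation",
]


@dataclass(frozen=True)
class TrueValues:
    """Cause-specific coefficients fitted to the full super-population."""

    beta_true_cvd: np.ndarray
    beta_true_cancer: np.ndarray
    beta_true_other: np.ndarray

    def for_cause(self, cause: int) -> np.ndarray:
        return (self.beta_true_cvd, self.beta_true_cancer,
                self.beta_true_other)[cause - 1]


def simulate_event(linpreds, rates, u1: float, u2: float):
    """One event time and type from the cause-specific exponential model.

    ``time = -log(u1) / sum_k rates_k * exp(linpreds_k)`` and the event
    type is drawn by inverting ``u2`` against the cumulative cause
    probabilities ``p_k = rates_k exp(lp_k) / sum_j rates_j exp(lp_j)``
    in fixed order (1, 2, 3).
    """
    t, d = simulate_events(np.atleast_2d(np.asarray(linpreds, dtype=float)),
                           rates, np.array([u1]), np.array([u2]))
    return float(t[0]), int(d[0])


def simulate_events(linpreds, rates, u1, u2):
    """Vectorized event simulation.

    Parameters
    ----------
    linpreds : (n, 3) array
        Per-subject linear predictors of the three cause-specific models.
    rates : (3,) array
        Positive baseline rates.
    u1, u2 : (n,) arrays of uniforms in (0, 1)
        ``u1`` drives the event time, ``u2`` the event type.

    Returns
    -------
    (time, event) : event times > 0 and event types in {1, 2, 3}.
    """
    linpreds = np.asarray(linpreds, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    if not np.all(np.isfinite(linpreds)):
        raise ValueError("non-finite linear predictor")
    haz = rates * np.exp(linpreds)          # (n, 3) cause-specific hazards
    total = haz.sum(axis=1)
    time = -np.log(u1) / total
    cum = np.cumsum(haz, axis=1) / total[:, None]
    event = 1 + (u2[:, None] > cum[:, :2]).sum(axis=1)
    return time, event


def calibrate_censoring(event_times, target: float, tol: float = 0.001,
                        max_iter: int = 100, seed=0):
    """Bisection for the exponential censoring rate.

    A single uniform draw ``u_i`` per subject is fixed across bisection
    iterations; the candidate censoring time is ``-log(u_i) / lam``, so
    the realized censored fraction ``mean(C < T)`` is non-decreasing in
    ``lam`` and the bisection objective is deterministic.  Stops when the
    realized fraction is within ``tol`` of ``target``.

    Returns ``(lam_censor, censor_times)``.
    """
    t = np.asarray(event_times, dtype=float)
    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    e = -np.log(rng.uniform(size=len(t)))   # unit-exponential draws

    def frac(lam):
        return float(np.mean(e / lam < t))

    lo, hi = 1e-12, 1.0 / np.median(t)
    for _ in range(200):
        if frac(hi) >= target:
            break
        hi *= 4.0
    else:
        raise RuntimeError(
            f"censoring target {target} not bracketed: frac({hi:.3g}) = {frac(hi):.4f}")
    if frac(lo) > target:
        raise RuntimeError(
            f"censoring target {target} not bracketed from below: "
            f"frac({lo:.3g}) = {frac(lo):.4f}")

    lam = hi
    for _ in range(max_iter):
        lam = np.sqrt(lo * hi)              # bisection on log(lam)
        f = frac(lam)
        if abs(f - target) <= tol:
            break
        if f < target:
            lo = lam
        else:
            hi = lam
    else:
        raise RuntimeError(
            f"censoring calibration did not reach tolerance {tol}: "
            f"bracket [{lo:.3g}, {hi:.3g}], realized {frac(lam):.4f}")
    return lam, e / lam


def apply_censoring(time, event, censor_times):
    """Observed time = min(T, C); event set to 0 where censored."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    censored = censor_times < time
    obs_time = np.where(censored, censor_times, time)
    obs_event = np.where(censored, 0, event)
    return obs_time, obs_event


def build_superpopulation(cfg: ScenarioConfig, cov_model: CovariateModel,
                          betas: CoefficientSet, fit_truth: bool = True):
    """Simulate the complete super-population and its "true" coefficients.

    Draws covariates, simulates event times/types from the cause-specific
    exponential hazards, calibrates exponential censoring to
    ``cfg.censor_target`` by bisection, and (optionally) fits the three
    cause-specific Cox models to the full population to define the
    scenario's true values.

    Returns ``(data, truth)`` where ``data`` has the 10 covariate columns
    plus ``time`` and ``event`` (0 = censored, 1 = cardiovascular,
    2 = cancer, 3 = other) and ``truth`` is a :class:`TrueValues`
    (``None`` when ``fit_truth`` is false).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2121]))
    data = generate_covariates(cov_model, cfg.n_super, rng)
    X = data.to_numpy()
    linpreds = X @ betas.stacked().T
    u1 = rng.uniform(size=cfg.n_super)
    u2 = rng.uniform(size=cfg.n_super)
    time, event = simulate_events(linpreds, cfg.rates, u1, u2)
    _, ctimes = calibrate_censoring(time, cfg.censor_target, seed=rng)
    obs_time, obs_event = apply_censoring(time, event, ctimes)
    data["time"] = obs_time
    data["event"] = obs_event.astype(int)

    truth = None
    if fit_truth:
        fits = [fit_cox(X, obs_time, (obs_event == k).astype(float),
                        names=COVARIATE_NAMES) for k in (1, 2, 3)]
        truth = TrueValues(beta_true_cvd=fits[0].beta,
                           beta_true_cancer=fits[1].beta,
                           beta_true_other=fits[2].beta)
    return data, truth
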