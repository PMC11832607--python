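"""Scenario configuration and the synthetic covariate model.

The simulation emulates a cohort of patients hospitalized with acute
myocardial infarction (AMI): 10 baseline covariates (5 continuous, 5
binary) feeding three cause-specific hazard models for cardiovascular
death, cancer death and death from other causes.  The real cohort's
covariate moments are not public, so this module ships one canonical
synthetic covariate model with clinically plausible scales and a mild
correlation structure; outcomes are generated from the published
log-hazard-ratio vectors (see :data:`DEFAULT_COEFFICIENTS`).

Covariates are drawn from a multivariate normal distribution; the last
five columns are dichotomized at the analytic ``(1 - prevalence)``
quantile of their own normal marginal, so the threshold does not depend
on the realized sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "COVARIATE_NAMES",
    "CONTINUOUS_NAMES",
    "BINARY_NAMES",
    "AMPUTABLE_NAMES",
    "CAUSE_NAMES",
    "RATE_TRIPLETS",
    "ScenarioConfig",
    "CovariateModel",
    "CoefficientSet",
    "DEFAULT_COEFFICIENTS",
    "default_covariate_model",
    "default_coefficient_set",
    "generate_covariates",
]

#: Covariate order used everywhere: 5 continuous then 5 binary.
COVARIATE_NAMES = [
    "age",
    "sbp",
    "heart_rate",
    "hemoglobin",
    "cholesterol",
    "female",
    "angina",
    "diabetes",
    "prev_ami",
    "smoker",
]
CONTINUOUS_NAMES = COVARIATE_NAMES[:5]
BINARY_NAMES = COVARIATE_NAMES[5:]

#: Variables that can be set missing.  Event time, event type, age and
#: sex come from administrative registries and are always complete.
AMPUTABLE_NAMES = [n for n in COVARIATE_NAMES if n not in ("age", "female")]

#: Event-type labels; index k-1 names event code k.
CAUSE_NAMES = ["cardiovascular", "cancer", "other"]

#: The five baseline-rate triplets of the factorial design
#: (lambda_cardiovascular, lambda_cancer, lambda_other).
RATE_TRIPLETS = [
    (1.0, 1.0 / 3.0, 1.0 / 3.0),
    (1.0, 0.5, 0.5),
    (1.0, 1.0, 1.0),
    (1.0, 2.0, 2.0),
    (1.0, 3.0, 3.0),
]

#: p_missing grid of the factorial design.
P_MISSING_GRID = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial simulation design.

    Parameters
    ----------
    lambda_cvd, lambda_cancer, lambda_other
        Baseline rates of the three cause-specific exponential hazards
        (events per unit time with all covariates at zero).
    p_missing
        Target proportion of incomplete records in the super-population.
    n_super
        Super-population size.
    n_sample
        Size of each random sample drawn without replacement.
    n_reps
        Number of simulation replicates.
    m_imputations
        Number of completed datasets per imputation strategy.
    censor_target
        Proportion of subjects censored, calibrated by bisection.
    seed
        Scenario-level RNG seed; per-replicate streams are spawned
        deterministically from it.
    """

    lambda_cvd: float = 1.0
    lambda_cancer: float = 1.0
    lambda_other: float = 1.0
    p_missing: float = 0.3
    n_super: int = 1_000_000
    n_sample: int = 1000
    n_reps: int = 1000
    m_imputations: int = 10
    censor_target: float = 0.25
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.lambda_cvd, self.lambda_cancer, self.lambda_other) <= 0:
            raise ValueError("baseline rates must be strictly positive")
        if not 0 <= self.p_missing < 1:
            raise ValueError("p_missing must lie in [0, 1)")
        if not 0 < self.censor_target < 1:
            raise ValueError("censor_target must lie in (0, 1)")
        if self.n_sample > self.n_super:
            raise ValueError("n_sample cannot exceed n_super")
        if self.m_imputations < 2:
            raise ValueError("at least 2 imputations are required for pooling")

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.lambda_cvd, self.lambda_cancer, self.lambda_other])

    def scaled_down(self, n_super: int = 100_000, n_reps: int = 100,
                    m_imputations: int = 5) -> "ScenarioConfig":
        """Desk-scale copy of the scenario (flagged downstream as scaled)."""
        return replace(self, n_super=n_super, n_reps=n_reps,
                       m_imputations=m_imputations)


@dataclass(frozen=True)
class CovariateModel:
    """Multivariate-normal covariate generator with dichotomized tail.

    ``mean``/``covariance`` describe the 10-dimensional latent normal;
    the last five coordinates are latent scores that become binary
    indicators with the given prevalences.
    """

    names: tuple = tuple(COVARIATE_NAMES)
    mean: np.ndarray = field(default=None)
    covariance: np.ndarray = field(default=None)
    binary_prevalence: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "binary_prevalence",
                           np.asarray(self.binary_prevalence, dtype=float))
        if self.mean.shape != (10,):
            raise ValueError("mean must be a 10-vector")
        if self.covariance.shape != (10, 10):
            raise ValueError("covariance must be 10x10")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if self.binary_prevalence.shape != (5,):
            raise ValueError("binary_prevalence must be a 5-vector")
        if not np.all((self.binary_prevalence > 0) & (self.binary_prevalence < 1)):
            raise ValueError("prevalences must lie strictly inside (0, 1)")

    def thresholds(self) -> np.ndarray:
        """Dichotomization cutoffs: the (1 - prevalence) quantile of each
        latent normal marginal (analytic, independent of sample size)."""
        mu = self.mean[5:]
        sd = np.sqrt(np.diag(self.covariance)[5:])
        return stats.norm.ppf(1.0 - self.binary_prevalence, loc=mu, scale=sd)


@dataclass(frozen=True)
class CoefficientSet:
    """Log-hazard-ratio vectors for the three cause-specific models,
    ordered as :data:`COVARIATE_NAMES`."""

    beta_cvd: np.ndarray
    beta_cancer: np.ndarray
    beta_other: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beta_cvd", "beta_cancer", "beta_other"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (10,):
                raise ValueError(f"{name} must be a 10-vector")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, v)

    def stacked(self) -> np.ndarray:
        """3x10 array, row k-1 = cause k."""
        return np.vstack([self.beta_cvd, self.beta_cancer, self.beta_other])


# Published log-hazard ratios of the three cause-specific hazard models
# estimated on the AMI cohort (cardiovascular, cancer, other).
DEFAULT_COEFFICIENTS = CoefficientSet(
    beta_cvd=np.array(
        [0.075, -0.007, 0.009, -0.008, -0.051, -0.045, 0.147, 0.297, 0.398, 0.226]
    ),
    beta_cancer=np.array(
        [0.062, -0.001, 0.007, -0.016, -0.042, -0.343, -0.203, 0.057, 0.0154, 0.584]
    ),
    beta_other=np.array(
        [0.077, -0.004, 0.009, -0.016, -0.073, -0.122, -0.038, 0.893, 0.297, 0.308]
    ),
)


def default_coefficient_set() -> CoefficientSet:
    """The published Table-1 coefficient set used as the default DGP."""
    return DEFAULT_COEFFICIENTS


# --- the packaged synthetic covariate model -------------------------------

_DEFAULT_SD = np.array([12.0, 25.0, 18.0, 1.8, 1.1, 1.0, 1.0, 1.0, 1.0, 1.0])
_DEFAULT_MEAN = np.array([65.0, 145.0, 80.0, 13.5, 5.0, 0.0, 0.0, 0.0, 0.0, 0.0])
_DEFAULT_PREVALENCE = np.array([0.35, 0.30, 0.25, 0.20, 0.30])

# Mild correlations (|r| <= 0.5); every row is strictly diagonally
# dominant, which guarantees positive definiteness.
_DEFAULT_CORR_ENTRIES = {
    ("age", "sbp"): 0.15,
    ("age", "hemoglobin"): -0.10,
    ("age", "cholesterol"): -0.10,
    ("age", "diabetes"): 0.10,
    ("age", "prev_ami"): 0.15,
    ("age", "smoker"): -0.15,
    ("sbp", "heart_rate"): 0.15,
    ("sbp", "diabetes"): 0.10,
    ("heart_rate", "smoker"): 0.10,
    ("hemoglobin", "female"): -0.30,
    ("cholesterol", "smoker"): 0.10,
    ("cholesterol", "diabetes"): 0.10,
    ("female", "smoker"): -0.15,
    ("angina", "prev_ami"): 0.30,
}


def default_covariate_model() -> CovariateModel:
    """The canonical packaged covariate model.

    A deterministic synthetic stand-in for the (unpublished) AMI cohort
    moments: continuous scales typical of an infarction registry, latent
    standard-normal scores for the five binary indicators, and a sparse
    mild correlation structure.  All acceptance-level experiments in this
    package reference this one model.
    """
    corr = np.eye(10)
    idx = {n: i for i, n in enumerate(COVARIATE_NAMES)}
    for (a, b), r in _DEFAULT_CORR_ENTRIES.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    cov = corr * np.outer(_DEFAULT_SD, _DEFAULT_SD)
    return CovariateModel(
        mean=_DEFAULT_MEAN.copy(),
        covariance=cov,
        binary_prevalence=_DEFAULT_PREVALENCE.copy(),
    )


def generate_covariates(model: CovariateModel, n: int,
                        seed: int | np.random.Generator) -> "pd.DataFrame":
    """Draw ``n`` covariate rows from ``model``.

    Columns 1-5 are the continuous variables; columns 6-10 are 0/1
    indicators obtained by thresholding the latent normal at the analytic
    ``(1 - prevalence)`` quantile, so the expected prevalence equals the
    target for every ``n``.

    Raises
    ------
    ValueError
        If the covariance matrix is not positive definite (the message
        reports the offending eigenvalues).
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    try:
        chol = np.linalg.cholesky(model.covariance)
    except np.linalg.LinAlgError:
        eig = np.linalg.eigvalsh(model.covariance)
        raise ValueError(
            "covariance matrix is not positive definite; "
            f"eigenvalues range [{eig.min():.4g}, {eig.max():.4g}]"
        ) from None
    z = rng.standard_normal((n, 10))
    latent = model.mean + z @ chol.T
    out = latent.copy()
    out[:, 5:] = (latent[:, 5:] > model.thresholds()).astype(float)
    return pd.DataFrame(out, columns=list(model.names))


# --- (de)serialization ----------------------------------------------------

def covariate_model_to_dict(model: CovariateModel) -> dict:
    return {
        "names": list(model.names),
        "mean": model.mean.tolist(),
        "covariance": model.covariance.tolist(),
        "binary_prevalence": model.binary_prevalence.tolist(),
    }


def covariate_model_from_dict(d: dict) -> CovariateModel:
    return CovariateModel(
        names=tuple(d.get("names", COVARIATE_NAMES)),
        mean=np.asarray(d["mean"]),
        covariance=np.asarray(d["covariance"]),
        binary_prevalence=np.asarray(d["binary_prevalence"]),
    )


def load_scenario(path: str) -> ScenarioConfig:
    """Read a ScenarioConfig from a YAML/JSON mapping file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ScenarioConfig(**raw)
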