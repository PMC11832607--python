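"""Multi-pattern MAR amputation of the eight incomplete covariates.

Missingness is induced with a multivariate amputation design in the
style of the `ampute` approach: every record is assigned to one of 67
missingness patterns (binary masks over the 8 amputable covariates) with
fixed library frequencies; within its pattern a record becomes
incomplete with probability given by a right-type logistic function of a
standardized weighted-sum score of the covariates the pattern leaves
observed (equal weights).  A single logistic intercept is calibrated by
bisection so the realized incomplete-record fraction equals the target
``p_missing``.  The mechanism never looks at the event time, the event
type, or the record's own amputed values, so missingness is MAR by
construction.

The real cohort's 67-pattern frequency table is unpublished; the packaged
library is a deterministic synthetic stand-in built from the published
marginal missingness prevalences (cholesterol 40.5% of all records,
smoker 13.4%, the rest around 1%, 48.1% of records incomplete overall):
pattern probabilities are the independence products of the
conditional-on-incomplete marginals, truncated to the 67 most probable
nonzero masks and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .population import AMPUTABLE_NAMES, COVARIATE_NAMES

__all__ = [
    "PatternLibrary",
    "MarMechanism",
    "default_pattern_library",
    "ampute",
    "MARGINAL_MISSINGNESS",
    "OVERALL_INCOMPLETE",
]

#: Published marginal missingness prevalence (share of ALL records) for
#: each amputable covariate in the AMI cohort.
MARGINAL_MISSINGNESS = {
    "sbp": 0.009,
    "heart_rate": 0.012,
    "hemoglobin": 0.012,
    "cholesterol": 0.405,
    "angina": 0.014,
    "diabetes": 0.004,
    "prev_ami": 0.016,
    "smoker": 0.134,
}

#: Published overall share of incomplete records in the AMI cohort.
OVERALL_INCOMPLETE = 0.481


@dataclass(frozen=True)
class PatternLibrary:
    """Missingness patterns (1 = set missing) and their frequencies."""

    patterns: np.ndarray        # (n_patterns, 8) 0/1 masks over AMPUTABLE_NAMES
    frequencies: np.ndarray     # (n_patterns,), nonnegative, sums to 1
    variable_names: tuple = tuple(AMPUTABLE_NAMES)

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=int)
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "patterns", p)
        object.__setattr__(self, "frequencies", f)
        if p.ndim != 2 or p.shape[1] != len(self.variable_names):
            raise ValueError("patterns must be (n_patterns, n_amputable)")
        if np.any(p.sum(axis=1) == 0):
            raise ValueError("all-zero pattern mask is not allowed")
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("frequencies must be nonnegative and sum to 1")
        if len(f) != len(p):
            raise ValueError("one frequency per pattern required")

    def marginal_missingness(self) -> pd.Series:
        """Per-variable P(missing | record incomplete): frequency-weighted
        share of patterns containing each variable."""
        m = self.frequencies @ self.patterns
        return pd.Series(m, index=list(self.variable_names))


@dataclass(frozen=True)
class MarMechanism:
    """Weighted-sum-score MAR mechanism with equal weights.

    For each pattern the score is the equal-weight sum of the
    standardized covariates the pattern leaves observed (so a record's
    own amputed values never influence its missingness); the outcome is
    always excluded.
    """

    equal_weights: bool = True
    outcome_excluded: bool = True

    def scores(self, covariates: pd.DataFrame, lib: PatternLibrary) -> np.ndarray:
        """(n, n_patterns) standardized weighted-sum scores."""
        z = (covariates - covariates.mean()) / covariates.std(ddof=0)
        z = z[list(COVARIATE_NAMES)].to_numpy()
        amp_idx = [COVARIATE_NAMES.index(v) for v in lib.variable_names]
        weights = np.ones((len(lib.patterns), len(COVARIATE_NAMES)))
        for g, mask in enumerate(lib.patterns):
            for j, v in zip(amp_idx, mask):
                if v:
                    weights[g, j] = 0.0     # amputed variables carry no weight
        s = z @ weights.T
        s = (s - s.mean(axis=0)) / s.std(axis=0, ddof=0)
        return s


def default_pattern_library(n_patterns: int = 67) -> PatternLibrary:
    """Deterministic synthetic stand-in for the cohort's pattern table.

    Conditional-on-incomplete marginals ``q_v`` are the published
    marginal prevalences divided by the overall incomplete share; the
    probability of each nonzero mask is the independence product
    ``prod q_v^m (1-q_v)^(1-m)``.  The ``n_patterns`` most probable masks
    are kept (ties broken lexicographically) and renormalized.  The
    single-variable cholesterol pattern dominates and implied marginal
    missingness ranks match the published ordering.
    """
    names = list(AMPUTABLE_NAMES)
    q = np.array([MARGINAL_MISSINGNESS[v] / OVERALL_INCOMPLETE for v in names])
    n_var = len(names)
    masks = ((np.arange(1, 2 ** n_var)[:, None] >> np.arange(n_var)) & 1).astype(int)
    logp = masks @ np.log(q) + (1 - masks) @ np.log1p(-q)
    # deterministic: sort by probability desc, then lexicographic mask
    order = np.lexsort(tuple(masks.T[::-1]) + (-logp,))
    keep = order[:n_patterns]
    freqs = np.exp(logp[keep])
    freqs /= freqs.sum()
    return PatternLibrary(patterns=masks[keep], frequencies=freqs,
                          variable_names=tuple(names))


def ampute(data: pd.DataFrame, lib: PatternLibrary | None = None,
           mech: MarMechanism | None = None, p_missing: float = 0.3,
           seed=0, tol: float = 0.002) -> pd.DataFrame:
    """Induce MAR missingness; returns a copy with NaN cells.

    Each record is assigned a candidate pattern (multinomial with the
    library frequencies) and an acceptance uniform; it becomes incomplete
    when ``u < expit(a + score)`` where the score is the record's
    standardized weighted-sum score for its pattern and the intercept
    ``a`` is found by bisection so the realized incomplete fraction is
    within ``tol`` of ``p_missing``.  Because the per-pattern scores are
    standardized, acceptance is (to first order) pattern-independent and
    realized pattern frequencies follow the library.

    ``time``, ``event``, age and sex are never amputed.
    """
    if not 0 <= p_missing < 1:
        raise ValueError("p_missing must lie in [0, 1)")
    out = data.copy()
    if p_missing == 0:
        return out
    lib = lib if lib is not None else default_pattern_library()
    mech = mech if mech is not None else MarMechanism()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(out)

    covs = out[list(COVARIATE_NAMES)]
    if covs.isna().any().any():
        raise ValueError("ampute requires complete input data")
    scores = mech.scores(covs, lib)                       # (n, n_patterns)
    assignment = rng.choice(len(lib.patterns), size=n, p=lib.frequencies)
    score = scores[np.arange(n), assignment]
    u = rng.uniform(size=n)

    def frac(a: float) -> float:
        return float(np.mean(u < expit(a + score)))

    lo, hi = -40.0, 40.0
    if not frac(lo) <= p_missing <= frac(hi):
        raise RuntimeError(f"p_missing={p_missing} unattainable on this sample")
    a = 0.0
    for _ in range(200):
        a = 0.5 * (lo + hi)
        f = frac(a)
        if abs(f - p_missing) <= tol:
            break
        if f < p_missing:
            lo = a
        else:
            hi = a
    else:
        raise RuntimeError(
            f"amputation calibration did not reach tolerance {tol}: "
            f"realized {frac(a):.4f}, target {p_missing}")

    incomplete = u < expit(a + score)
    amp_cols = list(lib.variable_names)
    mask_matrix = lib.patterns[assignment].astype(bool) & incomplete[:, None]
    vals = out[amp_cols].to_numpy(dtype=float)
    vals[mask_matrix] = np.nan
    out[amp_cols] = vals
    return out
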