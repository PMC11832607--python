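"""Outcome-derived predictors for the imputation models.

Following the standard advice for imputing covariates with censored
outcomes, the time component enters the imputation models through the
empirical (Nelson-Aalen) cumulative hazard evaluated at each record's
observed time.  With three competing event types there are three
cause-specific cumulative hazards ``H_k(t) = sum_{s <= t} d_k(s)/n(s)``
(``d_k(s)``: cause-k events at the distinct time ``s``; ``n(s)``:
at-risk count), plus the three event-type indicators.  Two predictor
strategies are supported:

``all_causes``
    9 other covariates + 3 hazards + 3 indicators + 27 hazard-by-
    covariate interactions (42 columns).
``primary_only``
    9 other covariates + the cardiovascular hazard and indicator + 9
    interactions (20 columns).

Hazards depend only on the observed time and event type, which are never
missing, so they are computed once per sample; interaction columns are
recomputed from current covariate values each chained-equations cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import COVARIATE_NAMES

__all__ = [
    "HazardFeatures",
    "nelson_aalen_cause_specific",
    "compute_hazard_features",
    "build_imputation_predictors",
    "predictor_names",
]

STRATEGIES = ("all_causes", "primary_only")


@dataclass(frozen=True)
class HazardFeatures:
    """Per-record cause-specific cumulative hazards and event indicators."""

    H: np.ndarray   # (n, 3): H_k at each record's observed time
    d: np.ndarray   # (n, 3): event-type indicators

    def frame(self) -> pd.DataFrame:
        cols = {f"H{k}": self.H[:, k - 1] for k in (1, 2, 3)}
        cols.update({f"d{k}": self.d[:, k - 1] for k in (1, 2, 3)})
        return pd.DataFrame(cols)


def nelson_aalen_cause_specific(time, event, cause: int) -> np.ndarray:
    """Cause-specific Nelson-Aalen hazard at each record's own time.

    ``H_k(t) = sum over distinct event times s <= t of d_k(s) / n(s)``,
    with ties aggregated at distinct times.  Events of other causes and
    censorings only deplete the risk set.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if len(time) == 0:
        raise ValueError("empty input")
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    e_s = (event[order] == cause).astype(float)

    new_group = np.empty(len(t_s), dtype=bool)
    new_group[0] = True
    np.not_equal(t_s[1:], t_s[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    group_start = np.flatnonzero(new_group)
    n_at_risk = len(t_s) - group_start                  # n(s) per distinct time
    d_k = np.bincount(group_id, weights=e_s, minlength=len(group_start))
    H_at_group = np.cumsum(d_k / n_at_risk)
    H_sorted = H_at_group[group_id]
    out = np.empty_like(H_sorted)
    out[order] = H_sorted
    return out


def compute_hazard_features(time, event) -> HazardFeatures:
    """All three cause-specific hazards and event indicators."""
    H = np.column_stack([nelson_aalen_cause_specific(time, event, k)
                         for k in (1, 2, 3)])
    d = np.column_stack([(np.asarray(event) == k).astype(float)
                         for k in (1, 2, 3)])
    return HazardFeatures(H=H, d=d)


def predictor_names(target: str, strategy: str) -> list[str]:
    """Ordered predictor column names for one target variable."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    others = [c for c in COVARIATE_NAMES if c != target]
    causes = (1, 2, 3) if strategy == "all_causes" else (1,)
    cols = list(others)
    cols += [f"H{k}" for k in causes]
    cols += [f"d{k}" for k in causes]
    cols += [f"H{k}:{c}" for k in causes for c in others]
    return cols


def build_imputation_predictors(data: pd.DataFrame, features: HazardFeatures,
                                target: str, strategy: str) -> np.ndarray:
    """Predictor matrix for imputing ``target`` under ``strategy``.

    Columns follow :func:`predictor_names`: the nine other covariates
    (current, possibly imputed, values), the selected cumulative hazards
    and event indicators, and the hazard-by-covariate interactions.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    others = [c for c in COVARIATE_NAMES if c != target]
    Xo = data[others].to_numpy(dtype=float)
    causes = (0, 1, 2) if strategy == "all_causes" else (0,)
    H = features.H[:, causes]
    d = features.d[:, causes]
    inter = (H[:, :, None] * Xo[:, None, :]).reshape(len(Xo), -1)
    return np.column_stack([Xo, H, d, inter])
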