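"""Association tests and external-validation harnesses.

Mutation/response associations use the two-sided Fisher exact test on 2x2
tables (two-sided by the minimum-likelihood convention: the p-value sums the
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed one). Continuous feature/response
associations use the Welch two-sample t-test. Predicted patient groups are
validated against survival outcomes by Kaplan-Meier curves with the
two-group log-rank test, and against observed binary responses by confusion
counts at a probability threshold plus the rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

from .models import auc as _rank_auc


@dataclass
class ContingencyTable2x2:
    """Rows: feature present/absent; columns: sensitive/resistant."""

    a: int  # present & sensitive
    b: int  # present & resistant
    c: int  # absent & sensitive
    d: int  # absent & resistant

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class SurvivalCohort:
    """Follow-up times, event indicators and predicted groups per patient."""

    time: np.ndarray
    event: np.ndarray  # 1 = event observed, 0 = censored
    group: np.ndarray  # "sensitive" / "resistant"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.group = np.asarray(self.group)
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and conditional odds ratio.

    A zero margin makes the table degenerate; by convention p = 1 and the
    odds ratio is NaN.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0, float("nan")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    orat = _conditional_or(arr, kind="conditional").statistic
    return float(p), float(orat)


def feature_response_ttest(
    feature_values: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t of a continuous feature between response classes.

    ``labels`` may be boolean or +/-1 (positive = sensitive). Zero variance
    in both groups leaves the statistic undefined (NaN, p = NaN).
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    pos = y > 0 if y.dtype != bool else y
    g1, g0 = x[pos], x[~pos]
    g1, g0 = g1[~np.isnan(g1)], g0[~np.isnan(g0)]
    if g1.size < 2 or g0.size < 2:
        raise ValueError("need >=2 observations per class")
    if np.var(g1) == 0 and np.var(g0) == 0:
        if g1.mean() == g0.mean():
            return 0.0, 1.0
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(g1, g0, equal_var=False)
    return float(t), float(p)


@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]  # per group: index time, column survival
    statistic: float
    p_value: float


def km_logrank(cohort: SurvivalCohort) -> KmResult:
    """Kaplan-Meier curves per predicted group and the two-group log-rank test."""
    groups = sorted(set(cohort.group.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-empty groups (got {groups})")
    if cohort.event.sum() == 0:
        raise ValueError("no events observed: log-rank p undefined")
    curves = {}
    for g in groups:
        m = cohort.group == g
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.time[m], cohort.event[m], label=str(g))
        curves[g] = kmf.survival_function_
    m = cohort.group == groups[0]
    res = logrank_test(
        cohort.time[m], cohort.time[~m], cohort.event[m], cohort.event[~m]
    )
    return KmResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


@dataclass
class DichotomousValidation:
    n_sensitive_correct: int
    n_sensitive: int
    n_resistant_correct: int
    n_resistant: int
    auc: float

    @property
    def sensitive_accuracy(self) -> float:
        return self.n_sensitive_correct / self.n_sensitive

    @property
    def resistant_accuracy(self) -> float:
        return self.n_resistant_correct / self.n_resistant


def dichotomous_validation(
    probabilities: np.ndarray,
    observed_sensitive: np.ndarray,
    threshold: float = 0.5,
) -> DichotomousValidation:
    """Confusion counts at a probability threshold plus the rank AUC.

    A probability exactly at the threshold is called resistant (the same
    conservative tie rule used for GI50 dichotomization).
    """
    p = np.asarray(probabilities, dtype=float)
    obs = np.asarray(observed_sensitive).astype(bool)
    called_sensitive = p > threshold
    return DichotomousValidation(
        n_sensitive_correct=int((called_sensitive & obs).sum()),
        n_sensitive=int(obs.sum()),
        n_resistant_correct=int((~called_sensitive & ~obs).sum()),
        n_resistant=int((~obs).sum()),
        auc=_rank_auc(p, obs),
    )
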