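"""Data-type performance comparison and baseline analyses.

Given multi-split evaluations of each (compound, data type, method), the
comparison takes the best AUC per cell (max over the two classifiers and,
for multi-level transcriptome platforms, over gene-level vs all-feature
variants), ranks the data types by mean AUC, tests the overall difference
with a one-way repeated-measures ANOVA (compounds as subjects) and all
pairwise differences with paired t-tests under Benjamini-Hochberg
correction.

A transcriptional-subtype baseline (one-hot subtype plus an ERBB2 flag,
same multi-split protocol) gives a reference AUC per compound; a compound is
"subtype sufficient" when the baseline exceeds 0.7 and the best omics model
improves on it by less than 0.1, and "omics adds" when the best model
exceeds 0.7 with an improvement of at least 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisConfig, SubtypeAnnotation, SUBTYPES
from .feature_prep import ResponseLabels
from .models import EvaluationResult, evaluate_multisplit

SUBTYPE_SUFFICIENT = "subtype_sufficient"
OMICS_ADDS = "omics_adds"
WEAK = "weak"


@dataclass
class DataTypeComparison:
    """Compounds x data-types grid of best AUCs with ranking statistics."""

    grid: pd.DataFrame  # compounds x data_types, NaN = missing cell
    ranking: list[str]  # data types, best mean AUC first
    mean_auc: pd.Series
    win_counts: pd.Series  # per data type; argmax ties credit every tied type
    overall_p: float  # repeated-measures ANOVA across data types
    pairwise: pd.DataFrame  # columns: type_a, type_b, t, p, p_adj


def best_auc_table(
    evaluations: list[EvaluationResult],
    data_type_of: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Best mean AUC per (compound, data type), max over methods/variants.

    Each evaluation carries its compound and ``data_types``; evaluations of
    the same (compound, data type) cell (e.g. LS-SVM and RF, or gene-level
    and all-feature variants tagged with the same data type) are collapsed by
    the maximum.
    """
    cells: dict[tuple[str, str], float] = {}
    for ev in evaluations:
        dt = "+".join(sorted(ev.data_types)) if ev.data_types else "combined"
        key = (ev.compound, dt)
        cells[key] = max(cells.get(key, -np.inf), ev.mean_auc)
    compounds = sorted({c for c, _ in cells})
    dtypes = sorted({d for _, d in cells})
    if len(dtypes) < 2:
        raise ValueError("need evaluations for at least 2 data types")
    grid = pd.DataFrame(np.nan, index=compounds, columns=dtypes)
    for (c, d), v in cells.items():
        grid.loc[c, d] = v
    return grid


def rank_data_types(grid: pd.DataFrame) -> DataTypeComparison:
    """Rank data types by mean best AUC with paired significance tests.

    Compounds with a missing cell are excluded from the affected pairwise
    test and from the repeated-measures ANOVA (which needs complete rows).
    """
    if grid.shape[1] < 2:
        raise ValueError("need at least 2 data types")
    if grid.shape[0] < 3:
        raise ValueError("need at least 3 compounds")
    mean_auc = grid.mean(axis=0, skipna=True).sort_values(ascending=False)
    ranking = list(mean_auc.index)

    row_max = grid.max(axis=1)
    wins = pd.Series(0, index=grid.columns, dtype=int)
    for comp in grid.index:
        row = grid.loc[comp]
        for dt in grid.columns[row == row_max[comp]]:
            wins[dt] += 1

    complete = grid.dropna(axis=0)
    overall_p = float("nan")
    if complete.shape[0] >= 3:
        long = complete.reset_index().melt(
            id_vars="index", var_name="data_type", value_name="auc"
        )
        if long.groupby("data_type")["auc"].var().max() > 0:
            overall_p = float(
                AnovaRM(long, "auc", "index", within=["data_type"])
                .fit().anova_table["Pr > F"].iloc[0]
            )
        else:
            overall_p = 1.0

    rows = []
    cols = list(grid.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = grid[[cols[i], cols[j]]].dropna()
            diff = pair[cols[i]] - pair[cols[j]]
            if len(diff) < 2:
                t, p = 0.0, 1.0
            elif np.allclose(diff.var(ddof=1), 0):
                # constant difference: no paired variance. Zero difference
                # means identical columns (p = 1); a constant non-zero shift
                # is as significant as a paired design can be.
                if np.allclose(diff.mean(), 0):
                    t, p = 0.0, 1.0
                else:
                    t, p = float(np.sign(diff.mean()) * np.inf), 0.0
            else:
                t, p = stats.ttest_rel(pair[cols[i]], pair[cols[j]])
            rows.append(
                {"type_a": cols[i], "type_b": cols[j],
                 "t": float(t), "p": float(p)}
            )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return DataTypeComparison(
        grid=grid, ranking=ranking, mean_auc=mean_auc, win_counts=wins,
        overall_p=overall_p, pairwise=pairwise,
    )


def subtype_feature_matrix(
    annotations: list[SubtypeAnnotation], lines: list[str]
) -> tuple[np.ndarray, list[str]]:
    """One-hot subtype indicators plus the ERBB2-amplification flag."""
    ann = {a.sample_id: a for a in annotations}
    missing = [s for s in lines if s not in ann]
    if missing:
        raise ValueError(f"no subtype annotation for lines: {missing[:5]}")
    levels = [s for s in SUBTYPES if s != "unknown"]
    X = np.zeros((len(lines), len(levels) + 1))
    for i, line in enumerate(lines):
        a = ann[line]
        if a.transcriptional_subtype in levels:
            X[i, levels.index(a.transcriptional_subtype)] = 1.0
        X[i, -1] = float(a.erbb2_amplified)
    names = [f"subtype_{s}" for s in levels] + ["erbb2_amplified"]
    return X, names


def subtype_baseline(
    labels: ResponseLabels,
    annotations: list[SubtypeAnnotation],
    n_splits: int = 100,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> EvaluationResult:
    """Multi-split AUC of a subtype-indicator-only classifier.

    Uses the same protocol as the omics models; raises when only one subtype
    is represented among the labeled lines (AUC undefined).
    """
    lines = sorted(labels.labels)
    X, _ = subtype_feature_matrix(annotations, lines)
    informative = X.std(axis=0) > 0
    if not informative.any():
        raise ValueError("single subtype present: baseline AUC undefined")
    ev = evaluate_multisplit(
        X, labels.y(lines), method="lssvm", n_splits=n_splits, seed=seed,
        config=config, select_features=False,
    )
    ev.compound = labels.compound
    ev.data_types = ["subtype"]
    return ev


def classify_subtype_sufficiency(
    best_omics_auc: float, subtype_auc: float
) -> str:
    """Partition compounds by what subtype alone achieves.

    ``subtype_sufficient``: subtype AUC > 0.7 and the best omics model adds
    less than 0.1. ``omics_adds``: best omics AUC > 0.7 and at least 0.1
    beyond subtype. Everything else is ``weak``.
    """
    eps = 1e-9  # boundary cases (delta exactly 0.1) count as a real gain
    delta = best_omics_auc - subtype_auc
    if best_omics_auc > 0.7 and delta >= 0.1 - eps:
        return OMICS_ADDS
    if subtype_auc > 0.7 and delta < 0.1:
        return SUBTYPE_SUFFICIENT
    return WEAK


def splice_delta(
    auc_all_features: pd.Series,
    auc_gene_level: pd.Series,
    flag_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-compound AUC gain of splice-aware features over gene level.

    Both series must come from the same splits. Compounds with a gain above
    ``flag_threshold`` are flagged as benefiting from splicing information.
    """
    common = auc_all_features.index.intersection(auc_gene_level.index)
    delta = auc_all_features[common] - auc_gene_level[common]
    out = pd.DataFrame(
        {"delta": delta, "flagged": delta > flag_threshold}, index=common
    )
    out.attrs["mean_delta"] = float(delta.mean()) if len(delta) else float("nan")
    return out


def gi50_tgi_concordance(
    labels_gi50: ResponseLabels, labels_tgi: ResponseLabels
) -> float:
    """Percent of lines assigned the same class by GI50- and TGI-based labels."""
    common = sorted(set(labels_gi50.labels) & set(labels_tgi.labels))
    if not common:
        raise ValueError("no common lines between the two labelings")
    agree = sum(
        labels_gi50.labels[s] == labels_tgi.labels[s] for s in common
    )
    return 100.0 * agree / len(common)
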