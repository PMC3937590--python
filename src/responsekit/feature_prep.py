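"""Feature filtering and response dichotomization.

Continuous omic matrices go through an unsupervised, label-blind filter
(variance quantile plus, where the platform provides them, detection-above-
background calls). Multi-level transcriptome datasets can then be reduced to
the single most response-discriminative feature per gene — a supervised step,
so it must run inside training folds only. Responses are dichotomized per
compound at the mean GI50 over the core cell-line set (lines with response
data and at least four molecular data types): lines strictly above the mean
-log10 GI50 are sensitive, the rest resistant (ties conservatively resistant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import MUTATION_PANEL_GENES, OmicDataset
from .dose_response import ResponseMatrix

logger = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass
class ResponseLabels:
    """Sensitive/resistant labels for one compound."""

    compound: str
    threshold: float  # mean -log10 GI50 over core lines
    labels: dict[str, str]
    core_lines: list[str]
    usable: bool = True  # False when only one class is present

    def y(self, lines: list[str]) -> np.ndarray:
        """Labels as +1 (sensitive) / -1 (resistant) over ``lines``."""
        return np.array(
            [1.0 if self.labels[s] == SENSITIVE else -1.0 for s in lines]
        )


@dataclass
class MutationPanel:
    """Binary lines x 7 matrix for the fixed recurrent-mutation gene panel."""

    cell_lines: list[str]
    values: np.ndarray  # (n_lines, 7), 0/1
    genes: tuple[str, ...] = MUTATION_PANEL_GENES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_lines), len(self.genes)):
            raise ValueError("mutation panel shape mismatch")
        vals = self.values[~np.isnan(self.values)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("mutation panel must be binary")


def variance_detection_filter(
    dataset: OmicDataset,
    variance_quantile: float = 0.25,
    detection_floor: float | None = None,
    min_detected_fraction: float = 0.5,
    max_missing_fraction: float = 0.2,
) -> OmicDataset:
    """Label-blind unsupervised filter on a continuous dataset.

    Drops features whose variance falls below the given quantile of the
    per-feature variance distribution, features detected above
    ``detection_floor`` in fewer than ``min_detected_fraction`` of samples
    (only when a floor is supplied — array platforms with detection calls, or
    a minimum-expression floor for sequencing data), and features missing in
    more than ``max_missing_fraction`` of samples.
    """
    variances = np.nanvar(dataset.values, axis=0, ddof=1)
    keep = np.ones(dataset.n_features, dtype=bool)
    if variance_quantile > 0:
        cut = np.nanquantile(variances, variance_quantile)
        keep &= variances >= cut
    keep &= variances > 0  # constant features never survive
    if detection_floor is not None:
        detected = np.nanmean(dataset.values > detection_floor, axis=0)
        keep &= detected >= min_detected_fraction
    missing = np.mean(np.isnan(dataset.values), axis=0)
    keep &= missing <= max_missing_fraction
    if not keep.any():
        raise ValueError(
            "no features survive filtering; relax variance_quantile or the "
            "detection thresholds"
        )
    return dataset.subset_features(np.flatnonzero(keep))


def two_sample_t(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t statistic per feature column against +/-1 labels.

    NaNs are ignored per group; all-constant columns get t = 0.
    """
    X = np.asarray(values, dtype=float)
    pos, neg = X[y > 0], X[y < 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        m1, m0 = np.nanmean(pos, axis=0), np.nanmean(neg, axis=0)
        v1 = np.nanvar(pos, axis=0, ddof=1)
        v0 = np.nanvar(neg, axis=0, ddof=1)
        n1 = np.sum(~np.isnan(pos), axis=0)
        n0 = np.sum(~np.isnan(neg), axis=0)
        se = np.sqrt(v1 / n1 + v0 / n0)
        t = (m1 - m0) / se
    t[~np.isfinite(t)] = 0.0
    return t


def best_feature_per_gene(
    dataset: OmicDataset, labels: ResponseLabels
) -> OmicDataset:
    """Keep the single most label-discriminative feature per gene.

    Supervised (uses the response labels), so apply inside training folds
    only. Genes whose features are all constant keep their gene-level feature
    if present, and are dropped otherwise.
    """
    lines = [s for s in dataset.sample_ids if s in labels.labels]
    sub = dataset.subset_samples(lines)
    t = np.abs(two_sample_t(sub.values, labels.y(lines)))
    by_gene: dict[str, list[int]] = {}
    for i, fid in enumerate(dataset.feature_ids):
        by_gene.setdefault(fid.gene, []).append(i)
    keep: list[int] = []
    for gene, idx in by_gene.items():
        t_gene = t[idx]
        if np.all(t_gene == 0):
            gene_level = [
                i for i in idx if dataset.feature_ids[i].level == "gene"
            ]
            if gene_level:
                keep.append(gene_level[0])
            continue
        keep.append(idx[int(np.argmax(t_gene))])
    return dataset.subset_features(sorted(keep))


def dichotomize(
    matrix: ResponseMatrix,
    compound: str,
    core_lines: list[str] | None = None,
) -> ResponseLabels:
    """Split lines into sensitive/resistant at the core-line mean GI50.

    The threshold is the arithmetic mean of -log10 GI50 over ``core_lines``
    (default: all lines with a GI50 for this compound); every line with a
    GI50 is then labeled against that threshold, sensitive strictly above it.
    """
    col = matrix.gi50[compound]
    present = col.dropna()
    if core_lines is None:
        core = list(present.index)
    else:
        core = [s for s in core_lines if s in present.index]
    if len(core) < 2:
        raise ValueError(
            f"{compound}: need >=2 core lines with GI50 (got {len(core)})"
        )
    threshold = float(present[core].mean())
    labels = {
        line: (SENSITIVE if gi > threshold else RESISTANT)
        for line, gi in present.items()
    }
    usable = len(set(labels.values())) == 2
    if not usable:
        logger.warning(
            "%s: single-class labeling (all GI50 on one side of %.4g); "
            "unusable for training", compound, threshold,
        )
    return ResponseLabels(
        compound=compound,
        threshold=threshold,
        labels=labels,
        core_lines=core,
        usable=usable,
    )


def core_line_set(
    matrix: ResponseMatrix, datasets: list[OmicDataset], min_data_types: int = 4
) -> list[str]:
    """Lines with response data and at least ``min_data_types`` omic datasets."""
    counts: dict[str, int] = {}
    for ds in datasets:
        for s in ds.sample_ids:
            counts[s] = counts.get(s, 0) + 1
    return sorted(
        s for s in matrix.cell_lines if counts.get(s, 0) >= min_data_types
    )


def build_mutation_panel(mutation_dataset: OmicDataset) -> MutationPanel:
    """Extract the fixed 7-gene panel columns; any absent gene is an error."""
    if mutation_dataset.data_type != "mutation":
        raise ValueError("expected a mutation dataset")
    gene_to_col = {
        fid.gene: i for i, fid in enumerate(mutation_dataset.feature_ids)
    }
    missing = [g for g in MUTATION_PANEL_GENES if g not in gene_to_col]
    if missing:
        raise ValueError(f"mutation dataset missing panel genes: {missing}")
    cols = [gene_to_col[g] for g in MUTATION_PANEL_GENES]
    return MutationPanel(
        cell_lines=list(mutation_dataset.sample_ids),
        values=mutation_dataset.values[:, cols].copy(),
    )
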