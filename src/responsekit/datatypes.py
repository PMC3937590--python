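"""Shared data model for the cell-line drug-response pipeline.

The pipeline moves through a small set of containers: raw growth-inhibition
plates (:class:`RawPlateRecord`), per-(line, compound) response measures on the
-log10(molar) GI50 scale, typed multi-omic feature matrices
(:class:`OmicDataset`), transcriptional-subtype annotations, trained response
signatures (:class:`Signature`), and the analysis configuration shared by the
command-line entry points.

Conventions
-----------
* Omic matrices are oriented samples x features in memory; on disk they follow
  the genomics convention of features x samples (readers transpose).
* Feature identifiers use the grammar ``GENE|level|detail`` so that multi-level
  transcriptome features (gene / transcript / exon / junction / boundary /
  intron) can be carried alongside array probes and proteins.
* Missing values are NaN; mutation matrices are strictly 0/1 (NaN allowed for
  unassayed cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

DATA_TYPES = (
    "expression_array",
    "exon_array",
    "rnaseq",
    "copy_number",
    "methylation",
    "protein_array",
    "mutation",
)

FEATURE_LEVELS = (
    "gene",
    "transcript",
    "exon",
    "junction",
    "boundary",
    "intron",
    "probe",
    "protein",
    "site",
)

SUBTYPES = ("luminal", "basal", "claudin_low", "normal_like", "unknown")

#: Genes of the fixed mutation panel (recurrently mutated in >=3% of breast
#: tumors and of the cell-line panel).
MUTATION_PANEL_GENES = (
    "TP53",
    "PIK3CA",
    "MLL3",
    "CDH1",
    "MAP2K4",
    "PTEN",
    "NCOR1",
)


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass(frozen=True)
class FeatureId:
    """Feature identifier carrying a gene symbol and a level tag.

    Serialized as ``GENE|level|detail`` (detail optional, e.g. an exon index
    or probe name). A bare ``GENE`` string is read as level ``gene``.
    """

    gene: str
    level: str = "gene"
    detail: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("feature id requires a gene symbol")
        if self.level not in FEATURE_LEVELS:
            raise ValueError(f"unknown feature level {self.level!r}")

    @classmethod
    def parse(cls, text: str) -> "FeatureId":
        parts = text.strip().split("|")
        if len(parts) == 1:
            return cls(parts[0])
        if len(parts) == 2:
            return cls(parts[0], parts[1])
        return cls(parts[0], parts[1], "|".join(parts[2:]))

    def __str__(self) -> str:
        if self.detail is not None:
            return f"{self.gene}|{self.level}|{self.detail}"
        if self.level != "gene":
            return f"{self.gene}|{self.level}"
        return self.gene


@dataclass
class OmicDataset:
    """A typed feature matrix over samples.

    ``values`` is samples x features with NaN marking missing entries.
    """

    data_type: str
    feature_ids: list[FeatureId]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data type {self.data_type!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_samples, n_features = self.values.shape
        if n_samples != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if n_features != len(self.feature_ids):
            raise ValueError("column count does not match feature_ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        keys = [str(f) for f in self.feature_ids]
        if len(set(keys)) != n_features:
            raise ValueError("feature_ids must be unique within a dataset")
        if self.data_type == "mutation":
            vals = self.values[~np.isnan(self.values)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("mutation matrices may contain only 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def feature_keys(self) -> list[str]:
        return [str(f) for f in self.feature_ids]

    def subset_features(self, index: Sequence[int]) -> "OmicDataset":
        idx = list(index)
        return OmicDataset(
            self.data_type,
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicDataset(
            self.data_type,
            list(self.feature_ids),
            list(sample_ids),
            self.values[idx, :].copy(),
        )


@dataclass(frozen=True)
class SubtypeAnnotation:
    """Transcriptional subtype and receptor status of one sample."""

    sample_id: str
    transcriptional_subtype: str
    erbb2_amplified: bool = False
    er_status: bool | None = None

    def __post_init__(self) -> None:
        if self.transcriptional_subtype not in SUBTYPES:
            raise ValueError(
                f"unknown subtype {self.transcriptional_subtype!r}"
            )


@dataclass
class RawPlateRecord:
    """One cell-line x compound growth-inhibition plate.

    Triplicate optical densities for untreated cells (``od0``) and for nine
    increasing drug concentrations (``treated_od``, 9x3), with plate and
    time-zero background readings. Missing wells are NaN.
    """

    cell_line: str
    compound: str
    drug_plate_id: str
    t0_plate_id: str
    background_ods: np.ndarray  # (2,)
    od0: np.ndarray  # (3,) untreated triplicate
    treated_od: np.ndarray  # (9, 3)
    t0_background_ods: np.ndarray  # (2,)
    t0_median_od: float
    concentrations: np.ndarray  # (9,), molar (ascending)
    units: str = "M"

    def __post_init__(self) -> None:
        self.background_ods = np.asarray(self.background_ods, dtype=float)
        self.od0 = np.asarray(self.od0, dtype=float)
        self.treated_od = np.asarray(self.treated_od, dtype=float)
        self.t0_background_ods = np.asarray(self.t0_background_ods, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.treated_od.shape != (9, 3):
            raise ValueError("treated_od must be 9 concentrations x 3 replicates")
        if self.concentrations.shape != (9,):
            raise ValueError("expected 9 concentrations")


@dataclass
class Signature:
    """A trained per-compound response model with its evaluation record.

    ``selected_features`` holds (feature id string, data type, weight or
    importance) triples. ``model_payload`` carries everything needed to score
    new profiles (standardization parameters and, for the LS-SVM, the dual
    solution); it is None for signatures read back from files that could not
    embed a model (random forests).
    """

    compound_id: str
    method: str  # "lssvm" | "rf"
    data_types_used: list[str]
    selected_features: list[tuple[str, str, float]]
    hyperparameters: dict
    per_split_auc: list[float]
    mean_auc: float
    gi50_threshold: float
    dynamic_range: float
    model_payload: dict | None = None

    def __post_init__(self) -> None:
        if self.method not in ("lssvm", "rf"):
            raise ValueError(f"unknown method {self.method!r}")
        for a in self.per_split_auc:
            if not (0.0 <= a <= 1.0):
                raise ValueError("AUC values must lie in [0, 1]")
        if self.per_split_auc:
            if not math.isclose(
                self.mean_auc,
                float(np.mean(self.per_split_auc)),
                abs_tol=1e-12,
            ):
                raise ValueError(
                    "mean_auc must equal the arithmetic mean of per_split_auc"
                )

    @property
    def has_model(self) -> bool:
        return self.model_payload is not None


@dataclass
class AnalysisConfig:
    """Tunable settings shared by the pipeline stages and the CLI.

    Defaults reflect a 48-line core panel: stratified 2/3 | 1/3 splits,
    feature-count grid spanning realistic signature sizes, and the report
    floors of model AUC > 0.7 and response probability > 0.65.
    """

    n_splits: int = 100
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    k_grid: tuple[int, ...] = (25, 50, 100, 200, 400)
    gamma_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    kernel: str = "linear"
    inner_folds: int = 3
    n_trees: int = 1000
    variance_quantile: float = 0.25
    min_detected_fraction: float = 0.5
    max_missing_fraction: float = 0.2
    sd_floor: float = 0.25
    offscale_max_fraction: float = 0.5
    resistant_quantile: float = 0.25
    auc_floor: float = 0.7
    prob_floor: float = 0.65
    coherence_r_threshold: float = 0.5
    coherence_n_perm: int = 9999
    exclude_normal_like: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["k_grid"] = list(self.k_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kwargs = dict(d)
        if "k_grid" in kwargs:
            kwargs["k_grid"] = tuple(kwargs["k_grid"])
        if "gamma_grid" in kwargs:
            kwargs["gamma_grid"] = tuple(kwargs["gamma_grid"])
        return cls(**kwargs)

    def with_updates(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
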