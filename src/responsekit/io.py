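"""Readers and writers for the package's plain-text dialects.

Plate files are delimited text with one plate per row, following the raw
growth-inhibition export layout (background ODs, untreated triplicate,
9 x 3 treated ODs, time-zero readings, nine concentrations, units). Omic
matrices are tab-delimited, features x rows / samples x columns on disk and
transposed to samples x features in memory. Signatures are versioned JSON.
Every writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    FeatureId,
    FormatError,
    OmicDataset,
    RawPlateRecord,
    Signature,
    SubtypeAnnotation,
)

SIGNATURE_FORMAT_VERSION = 1

PLATE_COLUMNS = (
    ["cellline", "compound", "drug_plate_id", "T0_plate_id",
     "background_od1", "background_od2",
     "od0.1", "od0.2", "od0.3"]
    + [f"od{j}.{r}" for j in range(1, 10) for r in (1, 2, 3)]
    + ["T0_background_od1", "T0_background_od2", "T0_median_od"]
    + [f"c{j}" for j in range(1, 10)]
    + ["units"]
)


def read_plate_file(path: str | Path) -> list[RawPlateRecord]:
    """Parse a raw drug-response plate file into records.

    Missing OD wells become NaN (masked). Raises :class:`FormatError` naming
    the first missing column, or a row-level error for a non-numeric
    concentration.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in PLATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"plate file missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        conc = []
        for j in range(1, 10):
            raw = row[f"c{j}"]
            try:
                conc.append(float(raw))
            except (TypeError, ValueError):
                raise FormatError(
                    f"row {i}: non-numeric concentration c{j}={raw!r}"
                ) from None
        treated = np.array(
            [[_od(row[f"od{j}.{r}"]) for r in (1, 2, 3)] for j in range(1, 10)]
        )
        records.append(
            RawPlateRecord(
                cell_line=str(row["cellline"]),
                compound=str(row["compound"]),
                drug_plate_id=str(row["drug_plate_id"]),
                t0_plate_id=str(row["T0_plate_id"]),
                background_ods=np.array(
                    [_od(row["background_od1"]), _od(row["background_od2"])]
                ),
                od0=np.array([_od(row[f"od0.{r}"]) for r in (1, 2, 3)]),
                treated_od=treated,
                t0_background_ods=np.array(
                    [_od(row["T0_background_od1"]), _od(row["T0_background_od2"])]
                ),
                t0_median_od=float(row["T0_median_od"]),
                concentrations=np.array(conc),
                units=str(row["units"]),
            )
        )
    return records


def _od(value) -> float:
    """One OD cell; blanks become NaN, anything else must be numeric."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    if isinstance(value, str) and value.strip() == "":
        return float("nan")
    return float(value)


def write_plate_file(records: list[RawPlateRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict = {
            "cellline": rec.cell_line,
            "compound": rec.compound,
            "drug_plate_id": rec.drug_plate_id,
            "T0_plate_id": rec.t0_plate_id,
            "background_od1": rec.background_ods[0],
            "background_od2": rec.background_ods[1],
        }
        for r in (1, 2, 3):
            row[f"od0.{r}"] = rec.od0[r - 1]
        for j in range(1, 10):
            for r in (1, 2, 3):
                row[f"od{j}.{r}"] = rec.treated_od[j - 1, r - 1]
        row["T0_background_od1"] = rec.t0_background_ods[0]
        row["T0_background_od2"] = rec.t0_background_ods[1]
        row["T0_median_od"] = rec.t0_median_od
        for j in range(1, 10):
            row[f"c{j}"] = rec.concentrations[j - 1]
        row["units"] = rec.units
        rows.append(row)
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_omic_matrix(path: str | Path, data_type: str) -> OmicDataset:
    """Read a tab-delimited features x samples matrix as an OmicDataset.

    The first column holds feature ids in the ``GENE|level|detail`` grammar;
    remaining columns are samples. The matrix is transposed to the in-memory
    samples x features orientation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids: {dupes[:5]}")
    feature_ids = [FeatureId.parse(str(t)) for t in df.index]
    values = df.to_numpy(dtype=float).T
    return OmicDataset(
        data_type=data_type,
        feature_ids=feature_ids,
        sample_ids=[str(c) for c in df.columns],
        values=values,
    )


def write_omic_matrix(dataset: OmicDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        dataset.values.T,
        index=[str(f) for f in dataset.feature_ids],
        columns=dataset.sample_ids,
    )
    df.to_csv(path, sep="\t", index_label="feature")


def read_annotations(path: str | Path) -> list[SubtypeAnnotation]:
    """Read a subtype annotation TSV (sample_id, subtype, erbb2, er)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "subtype", "erbb2_amplified"):
        if col not in df.columns:
            raise FormatError(f"annotation file missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        er = row.get("er_status")
        out.append(
            SubtypeAnnotation(
                sample_id=str(row["sample_id"]),
                transcriptional_subtype=str(row["subtype"]),
                erbb2_amplified=bool(row["erbb2_amplified"]),
                er_status=None if pd.isna(er) else bool(er),
            )
        )
    return out


def write_annotations(
    annotations: list[SubtypeAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "subtype": [a.transcriptional_subtype for a in annotations],
            "erbb2_amplified": [int(a.erbb2_amplified) for a in annotations],
            "er_status": [
                "" if a.er_status is None else int(a.er_status)
                for a in annotations
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def write_response_table(matrix, path: str | Path) -> None:
    """Write a ResponseMatrix as a long-format TSV.

    Columns: cell_line, compound, gi50, tgi, clamped, dynamic_range,
    retained. One row per (line, compound) pair with a GI50.
    """
    rows = []
    for comp in matrix.compounds:
        for line in matrix.cell_lines:
            gi = matrix.gi50.loc[line, comp]
            if pd.isna(gi):
                continue
            tgi = matrix.tgi.loc[line, comp]
            rows.append(
                {
                    "cell_line": line,
                    "compound": comp,
                    "gi50": gi,
                    "tgi": "" if pd.isna(tgi) else tgi,
                    "clamped": matrix.clamped.loc[line, comp],
                    "dynamic_range": matrix.dynamic_range[comp],
                    "retained": int(comp in matrix.retained),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_response_table(path: str | Path):
    """Read a long-format response TSV back into a ResponseMatrix."""
    from .dose_response import ResponseMatrix

    df = pd.read_csv(path, sep="\t")
    for col in ("cell_line", "compound", "gi50", "clamped"):
        if col not in df.columns:
            raise FormatError(f"response table missing column {col!r}")
    lines = sorted(df["cell_line"].astype(str).unique())
    compounds = sorted(df["compound"].astype(str).unique())
    gi50 = pd.DataFrame(np.nan, index=lines, columns=compounds)
    tgi = pd.DataFrame(np.nan, index=lines, columns=compounds)
    clamped = pd.DataFrame("", index=lines, columns=compounds, dtype=object)
    dyn = pd.Series(0.0, index=compounds)
    retained = set()
    for _, row in df.iterrows():
        line, comp = str(row["cell_line"]), str(row["compound"])
        gi50.loc[line, comp] = float(row["gi50"])
        if "tgi" in df.columns and not pd.isna(row["tgi"]):
            tgi.loc[line, comp] = float(row["tgi"])
        clamped.loc[line, comp] = str(row["clamped"])
        if "dynamic_range" in df.columns:
            dyn[comp] = float(row["dynamic_range"])
        if "retained" in df.columns and int(row["retained"]):
            retained.add(comp)
    return ResponseMatrix(
        gi50=gi50, tgi=tgi, clamped=clamped, dynamic_range=dyn,
        retained=sorted(retained) if retained else list(compounds),
    )


def write_signature(signature: Signature, path: str | Path) -> None:
    doc = {
        "format_version": SIGNATURE_FORMAT_VERSION,
        "compound_id": signature.compound_id,
        "method": signature.method,
        "data_types_used": signature.data_types_used,
        "selected_features": [
            [fid, dt, w] for fid, dt, w in signature.selected_features
        ],
        "hyperparameters": _jsonable(signature.hyperparameters),
        "per_split_auc": [float(a) for a in signature.per_split_auc],
        "mean_auc": float(signature.mean_auc),
        "gi50_threshold": float(signature.gi50_threshold),
        "dynamic_range": float(signature.dynamic_range),
        "model_payload": _jsonable(signature.model_payload),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_signature(path: str | Path) -> Signature:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupted signature file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise FormatError(f"{path} is not a signature file")
    if doc["format_version"] != SIGNATURE_FORMAT_VERSION:
        raise FormatError(
            f"signature format version {doc['format_version']} not supported "
            f"(expected {SIGNATURE_FORMAT_VERSION})"
        )
    return Signature(
        compound_id=doc["compound_id"],
        method=doc["method"],
        data_types_used=list(doc["data_types_used"]),
        selected_features=[
            (str(f), str(d), float(w)) for f, d, w in doc["selected_features"]
        ],
        hyperparameters=doc["hyperparameters"],
        per_split_auc=[float(a) for a in doc["per_split_auc"]],
        mean_auc=float(doc["mean_auc"]),
        gi50_threshold=float(doc["gi50_threshold"]),
        dynamic_range=float(doc["dynamic_range"]),
        model_payload=doc.get("model_payload"),
    )


def _jsonable(obj):
    """Recursively convert numpy containers/scalars for JSON output."""
    if obj is None:
        return None
    if isinstance(obj, dict):
        # keys starting with "_" hold runtime-only objects (e.g. a fitted
        # forest) that have no text representation
        return {
            k: _jsonable(v) for k, v in obj.items() if not k.startswith("_")
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(doc)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
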