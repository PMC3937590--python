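"""Synthetic cell-line panels, dose-response plates and tumor cohorts.

Every pipeline stage can be exercised without the deposited datasets by
generating a panel with known ground truth: lines carry a transcriptional
subtype (with ERBB2-amplified luminal/basal sub-fractions), omic matrices
combine subtype-marker shifts, planted response-associated features and
independent Gaussian noise, mutations in the 7-gene panel are Bernoulli with
subtype-dependent rates, and each planted compound defines a true
sensitivity class from which true GI50 values and raw OD plates are derived.

Planted compounds come in four flavors:

* ``feature`` — sensitivity is an independent latent coin; planted features
  are shifted by ``effect_size`` standard deviations in sensitive lines
  (orthogonal to subtype).
* ``subtype`` — sensitivity is determined by subtype membership; no features
  beyond the subtype markers carry signal.
* ``mixed`` — an even blend of both drivers.
* ``null`` — GI50 is pure noise; no feature is associated with response.

Plates invert the dose-response model: percent growth is linear in
log10(concentration) with its 50% crossing exactly at the true GI50, so the
noise-free round trip through background correction and log-linear
interpolation recovers the truth to interpolation tolerance, and true GI50s
placed outside the tested concentration range exercise the clamping flags.
All randomness flows from one seeded generator; outputs are bit-identical
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    FeatureId,
    MUTATION_PANEL_GENES,
    OmicDataset,
    RawPlateRecord,
    SubtypeAnnotation,
)

#: Subtype mix of the panel (luminal : basal : claudin-low : normal-like).
DEFAULT_SUBTYPE_PROPORTIONS = {
    "luminal": 0.44,
    "basal": 0.34,
    "claudin_low": 0.13,
    "normal_like": 0.09,
}

#: ERBB2-amplified fraction within each subtype.
ERBB2_RATES = {"luminal": 0.40, "basal": 0.26, "claudin_low": 0.0,
               "normal_like": 0.0}

#: Mutation probability of the panel genes by subtype (TP53 enriched in
#: basal/claudin-low, PIK3CA in luminal; the rest at a flat background rate).
MUTATION_RATES = {
    "TP53": {"luminal": 0.30, "basal": 0.80, "claudin_low": 0.70,
             "normal_like": 0.20},
    "PIK3CA": {"luminal": 0.40, "basal": 0.10, "claudin_low": 0.10,
               "normal_like": 0.20},
}
BACKGROUND_MUTATION_RATE = 0.10


@dataclass
class PlantedCompound:
    """Ground-truth description of one simulated compound."""

    name: str
    driver: str = "feature"  # feature | subtype | mixed | null | erbb2
    n_planted: int = 15
    planted_data_types: tuple[str, ...] = ("expression_array",)
    effect_size: float = 2.0  # SD units between classes
    gi50_base: float = 7.0  # -log10(molar)
    gi50_spread: float = 1.0  # class separation on the -log10 scale
    gi50_noise_sd: float = 0.25
    sensitive_subtypes: tuple[str, ...] = ("basal", "claudin_low")
    sensitive_fraction: float = 0.5


@dataclass
class SimulationDesign:
    """Study conditions for the synthetic panel."""

    n_lines: int = 48
    subtype_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS)
    )
    feature_counts: dict = field(
        default_factory=lambda: {
            "expression_array": 1000,
            "copy_number": 500,
            "methylation": 500,
        }
    )
    n_subtype_markers: int = 50  # per continuous data type
    subtype_marker_shift: float = 1.5  # SD units between subtypes
    compounds: list = field(
        default_factory=lambda: [PlantedCompound("drug_feature")]
    )
    concentrations: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-9, 1e-5, 9)
    )
    growth_slope: float = 50.0  # percent growth per decade of concentration
    od_cv: float = 0.0  # multiplicative OD noise
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        for c in self.compounds:
            if c.effect_size < 0:
                raise ValueError("effect sizes must be >= 0")


@dataclass
class CompoundTruth:
    """What the generator planted for one compound."""

    compound: PlantedCompound
    true_sensitive: pd.Series  # bool per line
    planted_features: list[tuple[str, str]]  # (feature key, data type)


@dataclass
class PanelTruth:
    """Full ground truth of a simulated panel."""

    datasets: dict[str, OmicDataset]
    annotations: list[SubtypeAnnotation]
    true_gi50: pd.DataFrame  # lines x compounds, -log10(molar)
    compounds: dict[str, CompoundTruth]
    design: SimulationDesign


def simulate_panel(design: SimulationDesign) -> PanelTruth:
    """Draw a cell-line panel with subtype structure and planted signal."""
    rng = np.random.default_rng(design.seed)
    lines = [f"line{i:03d}" for i in range(design.n_lines)]
    subtype_names = sorted(design.subtype_proportions)
    probs = np.array([design.subtype_proportions[s] for s in subtype_names])
    subtypes = rng.choice(subtype_names, size=design.n_lines, p=probs)
    erbb2 = np.array(
        [rng.random() < ERBB2_RATES.get(s, 0.0) for s in subtypes]
    )
    annotations = [
        SubtypeAnnotation(
            sample_id=line,
            transcriptional_subtype=s,
            erbb2_amplified=bool(e),
            er_status=bool(s == "luminal"),
        )
        for line, s, e in zip(lines, subtypes, erbb2)
    ]

    # --- sensitivity classes and true GI50 per compound -------------------
    true_gi50 = pd.DataFrame(
        np.nan, index=lines, columns=[c.name for c in design.compounds]
    )
    classes: dict[str, np.ndarray] = {}
    for comp in design.compounds:
        if comp.driver == "subtype":
            cls = np.isin(subtypes, comp.sensitive_subtypes)
        elif comp.driver == "erbb2":
            cls = erbb2.copy()
        elif comp.driver in ("feature", "null"):
            cls = rng.random(design.n_lines) < comp.sensitive_fraction
        elif comp.driver == "mixed":
            z = (
                0.5 * (np.isin(subtypes, comp.sensitive_subtypes) * 2.0 - 1.0)
                + 0.5 * rng.standard_normal(design.n_lines)
            )
            cls = z > 0
        else:
            raise ValueError(f"unknown driver {comp.driver!r}")
        classes[comp.name] = cls
        if comp.driver == "null":
            gi50 = comp.gi50_base + comp.gi50_noise_sd * rng.standard_normal(
                design.n_lines
            )
        else:
            gi50 = (
                comp.gi50_base
                + comp.gi50_spread * (cls.astype(float) - 0.5)
                + comp.gi50_noise_sd * rng.standard_normal(design.n_lines)
            )
        true_gi50[comp.name] = gi50

    # --- continuous omic datasets ----------------------------------------
    datasets: dict[str, OmicDataset] = {}
    truths: dict[str, CompoundTruth] = {
        c.name: CompoundTruth(
            compound=c,
            true_sensitive=pd.Series(classes[c.name], index=lines),
            planted_features=[],
        )
        for c in design.compounds
    }
    for dt in sorted(design.feature_counts):
        p = design.feature_counts[dt]
        prefix = {"expression_array": "EX", "copy_number": "CN",
                  "methylation": "ME", "rnaseq": "RS",
                  "exon_array": "EA", "protein_array": "PR"}.get(dt, "FT")
        values = rng.standard_normal((design.n_lines, p))
        # subtype markers: distinct mean per subtype for the first block
        n_mark = min(design.n_subtype_markers, p)
        shift = design.subtype_marker_shift
        marker_means = {
            s: shift * rng.standard_normal(n_mark) for s in subtype_names
        }
        for i, s in enumerate(subtypes):
            values[i, :n_mark] += marker_means[s]
        feature_ids = [FeatureId(f"{prefix}{j:05d}") for j in range(p)]
        if dt == "copy_number":
            # ERBB2 locus: amplified lines sit ~2 SD above the rest
            feature_ids[n_mark] = FeatureId("ERBB2")
            values[:, n_mark] = 2.0 * erbb2 + 0.5 * rng.standard_normal(
                design.n_lines
            )
        # planted response features, placed after the marker block
        cursor = n_mark + 1
        for comp in design.compounds:
            if comp.driver in ("subtype", "null", "erbb2"):
                continue
            if dt not in comp.planted_data_types:
                continue
            cls = classes[comp.name]
            for _ in range(comp.n_planted):
                if cursor >= p:
                    raise ValueError(
                        f"{dt}: not enough features to plant signal"
                    )
                values[:, cursor] += comp.effect_size * cls
                truths[comp.name].planted_features.append(
                    (str(feature_ids[cursor]), dt)
                )
                cursor += 1
        datasets[dt] = OmicDataset(
            data_type=dt, feature_ids=feature_ids, sample_ids=list(lines),
            values=values,
        )

    # --- mutation panel ----------------------------------------------------
    mut_genes = list(MUTATION_PANEL_GENES)
    mut = np.zeros((design.n_lines, len(mut_genes)))
    for j, gene in enumerate(mut_genes):
        rates = MUTATION_RATES.get(gene)
        for i, s in enumerate(subtypes):
            rate = rates[s] if rates else BACKGROUND_MUTATION_RATE
            mut[i, j] = float(rng.random() < rate)
    datasets["mutation"] = OmicDataset(
        data_type="mutation",
        feature_ids=[FeatureId(g) for g in mut_genes],
        sample_ids=list(lines),
        values=mut,
    )
    return PanelTruth(
        datasets=datasets, annotations=annotations, true_gi50=true_gi50,
        compounds=truths, design=design,
    )


# ---------------------------------------------------------------------------
# raw plates
# ---------------------------------------------------------------------------

_T0_SIGNAL = 200.0
_CONTROL_SIGNAL = 500.0
_BACKGROUND = 25.0


def _growth_at(x: np.ndarray, x50: float, slope: float) -> np.ndarray:
    """Percent growth linear in log10(concentration), 50% crossing at x50."""
    g = 50.0 + slope * (x50 - x)
    return np.maximum(g, -95.0)  # keep treated signal positive


def simulate_plates(
    true_gi50: pd.DataFrame, design: SimulationDesign
) -> list[RawPlateRecord]:
    """Generate plate records whose dose-response curves encode the true GI50s.

    Percent growth declines linearly in log10(concentration) at
    ``design.growth_slope`` percent per decade through (true GI50, 50%); the
    growth values are converted back to treated ODs through the two-branch
    growth definition, background is added, and (optionally) multiplicative
    OD noise at ``design.od_cv`` is applied. Truths outside the tested range
    produce off-scale curves that exercise the clamping flags.
    """
    rng = np.random.default_rng(design.seed + 1)
    conc = np.asarray(design.concentrations, dtype=float)
    x = np.log10(conc)
    records: list[RawPlateRecord] = []

    def noisy(value: float, n: int) -> np.ndarray:
        reps = np.full(n, value)
        if design.od_cv > 0:
            reps = reps * (1.0 + design.od_cv * rng.standard_normal(n))
        return reps

    for compound in true_gi50.columns:
        for plate_no, line in enumerate(true_gi50.index):
            gi = true_gi50.loc[line, compound]
            if np.isnan(gi):
                continue
            growth = _growth_at(x, -float(gi), design.growth_slope)
            treated = np.where(
                growth >= 0,
                _T0_SIGNAL + growth / 100.0 * (_CONTROL_SIGNAL - _T0_SIGNAL),
                _T0_SIGNAL * (1.0 + growth / 100.0),
            )
            records.append(
                RawPlateRecord(
                    cell_line=line,
                    compound=compound,
                    drug_plate_id=f"{compound}_p{plate_no:03d}",
                    t0_plate_id=f"{compound}_t0_{plate_no:03d}",
                    background_ods=np.full(2, _BACKGROUND),
                    od0=noisy(_CONTROL_SIGNAL, 3) + _BACKGROUND,
                    treated_od=np.stack(
                        [noisy(t, 3) + _BACKGROUND for t in treated]
                    ),
                    t0_background_ods=np.full(2, _BACKGROUND),
                    t0_median_od=_T0_SIGNAL + _BACKGROUND,
                    concentrations=conc,
                    units="M",
                )
            )
    return records


# ---------------------------------------------------------------------------
# tumor cohorts
# ---------------------------------------------------------------------------

def simulate_tumor_cohort(
    panel: PanelTruth,
    compound_name: str,
    n_patients: int = 300,
    responder_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, OmicDataset], pd.Series]:
    """Tumor profiles with a known responder subset for one planted compound.

    Patients are drawn with the same subtype-marker structure as the cell
    lines; the ``responder_fraction`` of them carry the compound's planted
    feature shifts. Returns (profiles per data type, true responder flags).
    """
    rng = np.random.default_rng(seed)
    truth = panel.compounds[compound_name]
    comp = truth.compound
    design = panel.design
    patients = [f"tumor{i:04d}" for i in range(n_patients)]
    responder = rng.random(n_patients) < responder_fraction

    subtype_names = sorted(design.subtype_proportions)
    probs = np.array([design.subtype_proportions[s] for s in subtype_names])
    subtypes = rng.choice(subtype_names, size=n_patients, p=probs)

    planted_by_type: dict[str, set[str]] = {}
    for key, dt in truth.planted_features:
        planted_by_type.setdefault(dt, set()).add(key)

    profiles: dict[str, OmicDataset] = {}
    for dt, ds in panel.datasets.items():
        if dt == "mutation":
            continue
        p = ds.n_features
        values = rng.standard_normal((n_patients, p))
        n_mark = min(design.n_subtype_markers, p)
        shift = design.subtype_marker_shift
        marker_means = {
            s: shift * rng.standard_normal(n_mark) for s in subtype_names
        }
        for i, s in enumerate(subtypes):
            values[i, :n_mark] += marker_means[s]
        planted = planted_by_type.get(dt, set())
        keys = ds.feature_keys()
        for j, key in enumerate(keys):
            if key in planted:
                values[:, j] += comp.effect_size * responder
        profiles[dt] = OmicDataset(
            data_type=dt, feature_ids=list(ds.feature_ids),
            sample_ids=patients, values=values,
        )
    return profiles, pd.Series(responder, index=patients, name=compound_name)
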