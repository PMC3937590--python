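"""Patient-level response prediction toolbox.

Cell-line-trained signatures are applied to tumor omic profiles to produce a
calibrated probability of response per (patient, compound). Per compound,
two probability cutoffs are chosen from the cohort's probability
distribution by normal mixture-model clustering (EM, component count by BIC,
cutoffs at the density intersections of adjacent components); each patient
is then assigned a tri-level status (resistant / intermediate / sensitive),
probabilities are rescaled so the two cutoffs land exactly at 1/3 and 2/3 of
the display scale, and compounds are ranked per patient by probability with
ties broken by the compound's in vitro GI50 dynamic range. Only compounds
whose model AUC exceeds 0.7, and for which at least one patient exceeds the
0.65 probability floor, enter the cohort report.

Signature transfer is sanity-checked by co-regulation coherence: the gene
pairs strongly correlated in the training cell lines should also be
correlated in the tumor cohort (Jaccard coefficient of the two edge sets,
permutation p-value over random gene sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .datatypes import OmicDataset, Signature

logger = logging.getLogger(__name__)

RESISTANT = "resistant"
INTERMEDIATE = "intermediate"
SENSITIVE = "sensitive"


@dataclass
class CutoffPair:
    """Per-compound probability cutoffs: resistant | intermediate | sensitive."""

    compound: str
    cutoff1: float
    cutoff2: float
    n_components: int
    log_likelihood: float
    fallback: str = ""  # "", "unimodal" or "em_failure"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cutoff1 < self.cutoff2 <= 1.0):
            raise ValueError(
                f"cutoffs must satisfy 0 <= c1 < c2 <= 1 "
                f"(got {self.cutoff1}, {self.cutoff2})"
            )


@dataclass
class PredictionReport:
    """Ranked per-patient compound recommendations plus cohort summaries."""

    per_patient: pd.DataFrame
    # columns: patient, rank, compound, probability, rescaled, status,
    #          model_auc, dynamic_range
    percent_sensitive: pd.Series  # per compound
    sensitive_counts: pd.Series  # per patient
    note: str = ""


@dataclass
class CoherenceResult:
    """Co-regulation transfer of a signature from cell lines to tumors."""

    jaccard: float
    p_value: float
    n_perm: int
    n_genes: int
    n_edges_cells: int
    n_edges_tumors: int


# ---------------------------------------------------------------------------
# applying signatures
# ---------------------------------------------------------------------------

def apply_signature(
    signature: Signature,
    tumor_profiles: dict[str, OmicDataset],
    min_overlap: float = 0.8,
) -> pd.Series:
    """Calibrated response probability per patient.

    Tumor features are standardized with the training-panel parameters stored
    in the signature; signature features absent from the profiles are imputed
    at the training mean (standardized 0) and logged. Per data type, at least
    ``min_overlap`` of the signature's features must be present, otherwise
    the signature is refused with the observed overlap fraction.
    """
    payload = signature.model_payload
    if payload is None:
        raise ValueError(
            f"signature for {signature.compound_id} carries no model payload"
        )
    keys = payload["feature_keys"]
    dtypes = payload["feature_data_types"]
    patients: list[str] | None = None
    for ds in tumor_profiles.values():
        ids = list(ds.sample_ids)
        patients = ids if patients is None else [p for p in patients if p in ids]
    if not patients:
        raise ValueError("tumor profiles share no patients")

    lookup: dict[tuple[str, str], np.ndarray] = {}
    for dt, ds in tumor_profiles.items():
        sub = ds.subset_samples(patients)
        for j, key in enumerate(sub.feature_keys()):
            lookup[(dt, key)] = sub.values[:, j]

    for dt in set(dtypes):
        idx = [i for i, d in enumerate(dtypes) if d == dt]
        present = sum((dt, keys[i]) in lookup for i in idx)
        overlap = present / len(idx)
        if overlap < min_overlap:
            raise ValueError(
                f"{signature.compound_id}: only {overlap:.0%} of "
                f"{dt} signature features present (< {min_overlap:.0%})"
            )

    means = np.asarray(payload["means"], dtype=float)
    stds = np.asarray(payload["stds"], dtype=float)
    n = len(patients)
    Z = np.zeros((n, len(keys)))
    n_imputed = 0
    for j, (dt, key) in enumerate(zip(dtypes, keys)):
        col = lookup.get((dt, key))
        if col is None:
            n_imputed += 1
            continue  # stays 0 = training mean after standardization
        z = (col - means[j]) / (stds[j] if stds[j] != 0 else 1.0)
        z[np.isnan(z)] = 0.0
        Z[:, j] = z
    if n_imputed:
        logger.info(
            "%s: %d/%d signature features mean-imputed",
            signature.compound_id, n_imputed, len(keys),
        )

    if payload["kind"] == "lssvm":
        from .models import LssvmModel

        model = LssvmModel(
            X_train=np.asarray(payload["X_train"], dtype=float),
            y_train=np.zeros(len(np.asarray(payload["alpha"]))),
            kernel=payload["kernel"],
            kernel_param=payload.get("kernel_param"),
            gamma=payload["gamma"],
            weights=np.ones(len(np.asarray(payload["alpha"]))),
            alpha=np.asarray(payload["alpha"], dtype=float),
            b=float(payload["b"]),
            calib_slope=float(payload["calib_slope"]),
            calib_offset=float(payload["calib_offset"]),
        )
        probs = model.predict_proba(Z)
    elif payload["kind"] == "rf":
        rf = payload.get("_estimator")
        if rf is None:
            raise ValueError(
                "random-forest signature was read from file without its "
                "fitted forest; retrain to predict"
            )
        probs = rf.predict_proba(Z)[:, 1]
    else:
        raise ValueError(f"unknown model payload kind {payload['kind']!r}")
    return pd.Series(probs, index=patients, name=signature.compound_id)


# ---------------------------------------------------------------------------
# cutoff selection by mixture clustering
# ---------------------------------------------------------------------------

def _gaussian_intersection(
    w1: float, m1: float, s1: float, w2: float, m2: float, s2: float
) -> float | None:
    """x between m1 < m2 where the two weighted normal densities are equal."""
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log((w1 * s2) / (w2 * s1))
    )
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        x = -c / b
        return x if m1 <= x <= m2 else None
    disc = b**2 - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (1.0, -1.0)]
    inside = [x for x in roots if m1 <= x <= m2]
    return inside[0] if inside else None


def select_cutoffs(
    probabilities: np.ndarray,
    compound: str = "",
    seed: int = 0,
    resistant_quantile: float = 0.25,
    fallback_quantiles: tuple[float, float] = (0.25, 0.75),
) -> CutoffPair:
    """Choose the two status cutoffs from the probability distribution.

    Normal mixtures with 1-3 components are fit by EM (multiple seeded
    restarts) and the component count picked by BIC. With 3 components the
    cutoffs are the density intersections between adjacent components; with
    2 components the single intersection separates intermediate from
    sensitive and the resistant boundary falls at ``resistant_quantile`` of
    the lower component. A unimodal fit (or EM failure) falls back to fixed
    sample quantiles, flagged.
    """
    p = np.asarray(probabilities, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 30:
        raise ValueError(f"need >=30 probabilities (got {p.size})")

    def _fallback(flag: str) -> CutoffPair:
        c1, c2 = np.quantile(p, fallback_quantiles)
        if not c1 < c2:
            c1 = max(0.0, float(np.mean(p)) - 0.1)
            c2 = min(1.0, float(np.mean(p)) + 0.1)
        return CutoffPair(
            compound=compound, cutoff1=float(np.clip(c1, 0, 1)),
            cutoff2=float(np.clip(c2, c1 + 1e-9, 1)), n_components=1,
            log_likelihood=float("nan"), fallback=flag,
        )

    if np.ptp(p) < 1e-9:
        return _fallback("unimodal")
    X = p.reshape(-1, 1)
    fits = {}
    for k in (1, 2, 3):
        try:
            gm = GaussianMixture(
                n_components=k, n_init=5, random_state=seed,
                covariance_type="full", reg_covar=1e-6,
            ).fit(X)
        except ValueError:  # pragma: no cover - EM failure guard
            continue
        if gm.converged_:
            fits[k] = (gm.bic(X), gm)
    if not fits:
        return _fallback("em_failure")
    k_best = min(fits, key=lambda k: fits[k][0])
    gm = fits[k_best][1]
    loglik = float(gm.score(X) * X.shape[0])
    if k_best == 1:
        return _fallback("unimodal")

    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    m = gm.means_.ravel()[order]
    s = np.sqrt(gm.covariances_.reshape(-1)[order])
    cuts = []
    for i in range(k_best - 1):
        x = _gaussian_intersection(
            w[i], m[i], s[i], w[i + 1], m[i + 1], s[i + 1]
        )
        cuts.append(x if x is not None else (m[i] + m[i + 1]) / 2.0)
    if k_best == 3:
        c1, c2 = cuts
    else:
        c2 = cuts[0]
        c1 = float(norm.ppf(resistant_quantile, loc=m[0], scale=s[0]))
        c1 = min(c1, c2 - 1e-6)
    c1 = float(np.clip(c1, 0.0, 1.0))
    c2 = float(np.clip(c2, 0.0, 1.0))
    if not c1 < c2:
        return _fallback("em_failure")
    return CutoffPair(
        compound=compound, cutoff1=c1, cutoff2=c2, n_components=int(k_best),
        log_likelihood=loglik,
    )


def assign_status(probability: float, cutoffs: CutoffPair) -> str:
    """Tri-level status; boundaries belong to the lower (conservative) band."""
    if probability <= cutoffs.cutoff1:
        return RESISTANT
    if probability <= cutoffs.cutoff2:
        return INTERMEDIATE
    return SENSITIVE


def rescale_probability(p: float, cutoffs: CutoffPair) -> float:
    """Piecewise-linear display rescaling anchored at 1/3 and 2/3.

    Maps [0, cutoff1] -> [0, 1/3], (cutoff1, cutoff2] -> (1/3, 2/3] and
    (cutoff2, 1] -> (2/3, 1], so each status occupies one display third;
    strictly increasing and continuous.
    """
    c1, c2 = cutoffs.cutoff1, cutoffs.cutoff2
    if p <= c1:
        return (p / c1) / 3.0 if c1 > 0 else 0.0
    if p <= c2:
        return (1.0 + (p - c1) / (c2 - c1)) / 3.0
    if c2 >= 1.0:
        return 1.0
    return (2.0 + (p - c2) / (1.0 - c2)) / 3.0


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_compounds(
    probabilities: pd.DataFrame,
    signatures: dict[str, Signature],
    cutoffs: dict[str, CutoffPair],
    auc_floor: float = 0.7,
    prob_floor: float = 0.65,
) -> PredictionReport:
    """Build the per-patient ranked treatment report.

    ``probabilities`` is patients x compounds. Compounds must pass the model
    AUC floor and have at least one patient above the probability floor to
    enter the report. Within a patient, compounds are ordered by descending
    probability, ties broken by descending GI50 dynamic range and then by
    compound id, making the report deterministic and independent of input
    order.
    """
    eligible = []
    for comp in probabilities.columns:
        sig = signatures.get(comp)
        if sig is None or not (sig.mean_auc > auc_floor):
            continue
        if not (probabilities[comp] > prob_floor).any():
            continue
        eligible.append(comp)
    if not eligible:
        return PredictionReport(
            per_patient=pd.DataFrame(
                columns=["patient", "rank", "compound", "probability",
                         "rescaled", "status", "model_auc", "dynamic_range"]
            ),
            percent_sensitive=pd.Series(dtype=float),
            sensitive_counts=pd.Series(dtype=int),
            note=(
                f"no compound passed model AUC > {auc_floor} with at least "
                f"one patient above probability {prob_floor}"
            ),
        )
    rows = []
    for patient in probabilities.index:
        entries = []
        for comp in eligible:
            p = float(probabilities.loc[patient, comp])
            sig = signatures[comp]
            entries.append(
                {
                    "patient": patient,
                    "compound": comp,
                    "probability": p,
                    "rescaled": rescale_probability(p, cutoffs[comp]),
                    "status": assign_status(p, cutoffs[comp]),
                    "model_auc": sig.mean_auc,
                    "dynamic_range": sig.dynamic_range,
                }
            )
        entries.sort(
            key=lambda e: (-e["probability"], -e["dynamic_range"], e["compound"])
        )
        for rank, e in enumerate(entries, start=1):
            e["rank"] = rank
            rows.append(e)
    per_patient = pd.DataFrame(
        rows,
        columns=["patient", "rank", "compound", "probability", "rescaled",
                 "status", "model_auc", "dynamic_range"],
    )
    sens = per_patient["status"] == SENSITIVE
    percent_sensitive = (
        per_patient[["compound"]].assign(s=sens).groupby("compound")["s"]
        .mean() * 100.0
    ).reindex(sorted(eligible))
    sensitive_counts = (
        per_patient[["patient"]].assign(s=sens).groupby("patient")["s"]
        .sum().astype(int)
    ).reindex(list(probabilities.index), fill_value=0)
    return PredictionReport(
        per_patient=per_patient,
        percent_sensitive=percent_sensitive,
        sensitive_counts=sensitive_counts,
    )


# ---------------------------------------------------------------------------
# signature coherence transfer
# ---------------------------------------------------------------------------

def _edge_set(values: np.ndarray, r_threshold: float) -> set[tuple[int, int]]:
    """Unordered index pairs with |Pearson r| above the threshold."""
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(values, rowvar=False)
    R = np.nan_to_num(R)
    n = R.shape[0]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if abs(R[i, j]) > r_threshold:
                edges.add((i, j))
    return edges


def signature_coherence(
    signature_genes: list[str],
    cell_line_expr: OmicDataset,
    tumor_expr: OmicDataset,
    r_threshold: float = 0.5,
    n_perm: int = 9999,
    seed: int = 0,
) -> CoherenceResult:
    """Jaccard overlap of co-regulation edges in cell lines versus tumors.

    An edge joins two signature genes whose expression correlates with
    |r| > ``r_threshold``; the edge sets are computed independently in the
    two matrices and compared by Jaccard coefficient. The permutation null
    redraws random gene sets of equal size from the genes shared by both
    matrices; p = (1 + #null >= J) / (1 + n_perm).
    """
    genes_cells = {f.gene: i for i, f in enumerate(cell_line_expr.feature_ids)}
    genes_tumors = {f.gene: i for i, f in enumerate(tumor_expr.feature_ids)}
    shared = sorted(set(genes_cells) & set(genes_tumors))
    genes = [g for g in signature_genes if g in genes_cells and g in genes_tumors]
    if len(genes) < 5:
        raise ValueError(
            f"need >=5 signature genes present in both matrices (got {len(genes)})"
        )

    def jaccard_for(gene_list: list[str]) -> tuple[float, int, int]:
        vc = cell_line_expr.values[:, [genes_cells[g] for g in gene_list]]
        vt = tumor_expr.values[:, [genes_tumors[g] for g in gene_list]]
        ec = _edge_set(vc, r_threshold)
        et = _edge_set(vt, r_threshold)
        union = ec | et
        if not union:
            return float("nan"), 0, 0
        return len(ec & et) / len(union), len(ec), len(et)

    J, n_ec, n_et = jaccard_for(genes)
    if np.isnan(J):
        raise ValueError("empty edge union: coherence undefined")
    rng = np.random.default_rng(seed)
    null_ge = 0
    for _ in range(n_perm):
        draw = list(rng.choice(shared, size=len(genes), replace=False))
        Jn, _, _ = jaccard_for(draw)
        if not np.isnan(Jn) and Jn >= J:
            null_ge += 1
    p = (1 + null_ge) / (1 + n_perm)
    return CoherenceResult(
        jaccard=float(J), p_value=float(p), n_perm=n_perm,
        n_genes=len(genes), n_edges_cells=n_ec, n_edges_tumors=n_et,
    )
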