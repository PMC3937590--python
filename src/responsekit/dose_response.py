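"""GI50 / TGI estimation from raw growth-inhibition plates.

A plate yields background-corrected signals: T0 (time-zero), C (untreated
control) and T(j) at nine drug concentrations. Percent growth follows the
two-branch convention used for growth-inhibition screening endpoints::

    growth = 100 * (T - T0) / (C - T0)   if T >= T0   (net growth)
    growth = 100 * (T - T0) / T0         if T <  T0   (net kill)

so growth is 100 for untreated-like wells, 0 at time-zero stasis (TGI) and
-100 for a complete kill. GI50 is the concentration at which growth crosses
50, found by linear interpolation in log10(concentration); TGI is the
crossing at 0. Both are reported as -log10(molar), so larger means more
potent. Crossings outside the tested range are clamped to the range edge and
flagged, preserving the censoring information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import RawPlateRecord

logger = logging.getLogger(__name__)

CLAMP_NONE = "none"
CLAMP_AT_MIN = "at_min"
CLAMP_AT_MAX = "at_max"


class CurveError(ValueError):
    """A plate cannot yield a usable growth curve."""


@dataclass
class GrowthCurve:
    """Background-corrected summary of one plate."""

    cell_line: str
    compound: str
    concentrations: np.ndarray  # usable concentrations, molar, ascending
    t0: float
    control: float  # C, untreated
    treated: np.ndarray  # T(j), same length as concentrations

    @property
    def growth(self) -> np.ndarray:
        return np.array(
            [growth_percent(t, self.t0, self.control) for t in self.treated]
        )


@dataclass
class ResponseMeasure:
    """GI50/TGI of one (cell line, compound) pair, -log10(molar)."""

    cell_line: str
    compound: str
    gi50: float
    tgi: float | None
    clamped: str = CLAMP_NONE
    replicate_count: int = 1


@dataclass
class ResponseMatrix:
    """Lines x compounds response grid with per-compound dynamic ranges.

    ``gi50``/``tgi`` are DataFrames (lines x compounds, NaN where absent),
    ``clamped`` the matching clamp-flag frame, ``dynamic_range`` a per-compound
    Series (max - min of -log10 GI50 over lines with unclamped values) and
    ``retained`` the compound list surviving the low-variation filter.
    """

    gi50: pd.DataFrame
    tgi: pd.DataFrame
    clamped: pd.DataFrame
    dynamic_range: pd.Series
    retained: list[str] = field(default_factory=list)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.gi50.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.gi50.columns)


def correct_background(record: RawPlateRecord) -> GrowthCurve:
    """Background-correct one plate and summarize triplicates by median.

    Concentrations where all three treated replicates are masked are dropped
    with a warning; a control signal <= 0 after correction rejects the plate.
    """
    bg = np.nanmean(record.background_ods)
    t0_bg = np.nanmean(record.t0_background_ods)
    if np.isnan(bg) or np.isnan(t0_bg):
        raise CurveError(
            f"{record.cell_line}/{record.compound}: no background readings"
        )
    control = float(np.nanmedian(record.od0 - bg))
    if np.isnan(control) or control <= 0:
        raise CurveError(
            f"{record.cell_line}/{record.compound}: control signal "
            f"{control} <= 0 after background correction"
        )
    t0 = float(record.t0_median_od - t0_bg)
    corrected = record.treated_od - bg
    usable_conc, treated = [], []
    for j in range(corrected.shape[0]):
        reps = corrected[j][~np.isnan(corrected[j])]
        if reps.size == 0:
            logger.warning(
                "%s/%s: all replicates masked at concentration %g; excluded",
                record.cell_line, record.compound, record.concentrations[j],
            )
            continue
        usable_conc.append(record.concentrations[j])
        treated.append(float(np.median(reps)))
    return GrowthCurve(
        cell_line=record.cell_line,
        compound=record.compound,
        concentrations=np.array(usable_conc),
        t0=t0,
        control=control,
        treated=np.array(treated),
    )


def growth_percent(T: float, T0: float, C: float) -> float:
    """Two-branch percent growth; continuous at T = T0, bounded below by -100.

    Requires a growing control (C > T0) and positive time-zero signal.
    """
    if T0 <= 0:
        raise CurveError(f"time-zero signal must be positive (got {T0})")
    if C <= T0:
        raise CurveError(
            f"control ({C}) did not grow beyond time zero ({T0}); "
            "growth undefined"
        )
    if T >= T0:
        return 100.0 * (T - T0) / (C - T0)
    # clamp guards the -100 complete-kill bound against rounding
    return max(-100.0, 100.0 * (T - T0) / T0)


def interpolate_crossing(
    concentrations: np.ndarray,
    growth_values: np.ndarray,
    level: float,
) -> tuple[float, str]:
    """Find where growth crosses ``level``; return (-log10 molar, clamp flag).

    Interpolation is linear in log10(concentration) over the first (lowest
    concentration) bracketing pair. If growth at the lowest concentration is
    already <= level the value is clamped to that edge (flag ``at_min``); if
    growth never reaches the level it is clamped to the highest tested
    concentration (flag ``at_max``).
    """
    conc = np.asarray(concentrations, dtype=float)
    g = np.asarray(growth_values, dtype=float)
    ok = ~(np.isnan(conc) | np.isnan(g))
    conc, g = conc[ok], g[ok]
    if conc.size < 2:
        raise CurveError("need at least 2 usable concentrations")
    if np.any(np.diff(conc) <= 0):
        raise CurveError("concentrations must be strictly increasing")
    x = np.log10(conc)
    if g[0] <= level:
        return float(-x[0]), CLAMP_AT_MIN
    for j in range(conc.size - 1):
        lo, hi = g[j], g[j + 1]
        if (lo - level) * (hi - level) <= 0 and lo != hi:
            t = (level - lo) / (hi - lo)
            return float(-(x[j] + t * (x[j + 1] - x[j]))), CLAMP_NONE
        if lo == level == hi:
            return float(-x[j]), CLAMP_NONE
    return float(-x[-1]), CLAMP_AT_MAX


def measure_response(curve: GrowthCurve) -> ResponseMeasure:
    """GI50 (level 50) and TGI (level 0) of one plate's growth curve."""
    gi50, clamp = interpolate_crossing(curve.concentrations, curve.growth, 50.0)
    try:
        tgi, _ = interpolate_crossing(curve.concentrations, curve.growth, 0.0)
    except CurveError:
        tgi = None
    return ResponseMeasure(
        cell_line=curve.cell_line,
        compound=curve.compound,
        gi50=gi50,
        tgi=tgi,
        clamped=clamp,
    )


def build_response_matrix(records: list[RawPlateRecord]) -> ResponseMatrix:
    """Aggregate plate records into the lines x compounds response grid.

    Replicate plates of one (line, compound) pair are combined by the median
    GI50 (and median TGI); clamp flags are kept only when all replicate plates
    agree. Rows and columns are ordered lexicographically, so the result is
    invariant to input record order. Unusable plates (dead control, too few
    points) are skipped with a warning.
    """
    measures: dict[tuple[str, str], list[ResponseMeasure]] = {}
    for rec in records:
        try:
            m = measure_response(correct_background(rec))
        except CurveError as exc:
            logger.warning("skipping plate: %s", exc)
            continue
        measures.setdefault((m.cell_line, m.compound), []).append(m)

    lines = sorted({k[0] for k in measures})
    compounds = sorted({k[1] for k in measures})
    gi50 = pd.DataFrame(np.nan, index=lines, columns=compounds)
    tgi = pd.DataFrame(np.nan, index=lines, columns=compounds)
    clamped = pd.DataFrame("", index=lines, columns=compounds, dtype=object)
    for (line, comp), plate_measures in measures.items():
        gi_vals = sorted(m.gi50 for m in plate_measures)
        gi50.loc[line, comp] = float(np.median(gi_vals))
        tgi_vals = [m.tgi for m in plate_measures if m.tgi is not None]
        if tgi_vals:
            tgi.loc[line, comp] = float(np.median(tgi_vals))
        flags = {m.clamped for m in plate_measures}
        clamped.loc[line, comp] = flags.pop() if len(flags) == 1 else CLAMP_NONE

    dynamic_range = pd.Series(0.0, index=compounds)
    for comp in compounds:
        vals = gi50[comp][(clamped[comp] == CLAMP_NONE) & gi50[comp].notna()]
        if len(vals) >= 2:
            dynamic_range[comp] = float(vals.max() - vals.min())
    return ResponseMatrix(
        gi50=gi50, tgi=tgi, clamped=clamped, dynamic_range=dynamic_range,
        retained=list(compounds),
    )


def filter_low_variation(
    matrix: ResponseMatrix,
    sd_floor: float = 0.25,
    offscale_max_fraction: float = 0.5,
) -> list[str]:
    """Compounds whose response varies enough across the panel.

    Retains compounds with an SD of -log10 GI50 of at least ``sd_floor`` and a
    fraction of clamped (off-scale) measurements of at most
    ``offscale_max_fraction``. Updates ``matrix.retained`` and returns the
    retained compound list.
    """
    retained = []
    for comp in matrix.compounds:
        vals = matrix.gi50[comp].dropna()
        if len(vals) < 2:
            continue
        flags = matrix.clamped[comp][vals.index]
        off_fraction = float((flags != CLAMP_NONE).mean())
        if vals.std(ddof=1) >= sd_floor and off_fraction <= offscale_max_fraction:
            retained.append(comp)
    matrix.retained = retained
    return retained
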