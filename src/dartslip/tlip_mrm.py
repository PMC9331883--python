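"""Targeted limited-proteolysis (t-LiP-MRM) quantification and region mapping.

The t-LiP design compares four conditions per peptide: a trypsin-only digest
(positive control, every fully tryptic peptide intact), a subtilisin+trypsin
double digest with vehicle (negative control), and double digests after
incubation with the ligand at one or more doses. Peptides whose area drops
significantly in the double digest are subtilisin-sensitive ("LiP peptides");
LiP peptides whose area recovers under ligand treatment mark regions the
ligand shields from proteolysis. Protected peptides are merged into intervals
and intersected with the protein's structural annotation track.

Peak areas arrive either pre-integrated (long-form table) or as time/intensity
chromatogram traces integrated here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_chem import AnnotationInterval, AnnotationKind, ProteinRecord

log = logging.getLogger(__name__)

TRYPSIN_ONLY = "trypsin_only"
DD_VEHICLE = "double_digest_vehicle"
DD_DOSE = "double_digest_dose"

#: canonical columns of a long-form peak-area table
AREA_COLUMNS = ["peptide_id", "transition_id", "condition", "dose_uM", "replicate_id", "area"]


@dataclass
class ChromTrace:
    """A single MRM chromatogram: intensity vs time for one transition."""

    peptide_id: str
    transition_id: str
    condition: str
    replicate_id: str
    time: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # counts, >= 0
    dose_uM: float = float("nan")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity vectors differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time vector must be strictly increasing")


@dataclass(frozen=True)
class PeakArea:
    peptide_id: str
    transition_id: str
    condition: str
    replicate_id: str
    area: float
    dose_uM: float = float("nan")


@dataclass(frozen=True)
class LiPSelection:
    peptide_id: str
    is_lip: bool
    p_value: float
    mean_ratio_dd_vs_tryp: float


@dataclass(frozen=True)
class FoldChange:
    peptide_id: str
    dose: float
    fc: float
    p_value: float


@dataclass(frozen=True)
class RegionReport:
    """Merged ligand-protected intervals and their structural-annotation overlaps."""

    protected_intervals: tuple[tuple[int, int], ...]
    overlaps: tuple[tuple[tuple[int, int], str, int], ...]  # (interval, name, n residues)
    residue_hits: tuple[str, ...] = ()  # point annotations inside a protected interval


# ---------------------------------------------------------------------------
# peak integration


def integrate_peak(
    trace: ChromTrace,
    window: tuple[float, float],
    baseline: str = "none",
) -> PeakArea:
    """Trapezoidal area of a chromatographic peak over ``window`` (minutes).

    ``baseline='linear_endpoints'`` subtracts the chord between the signal at
    the window endpoints; the background-corrected signal is floored at zero
    pointwise before integration.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must satisfy t0 < t1")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError(
            f"window [{t0}, {t1}] outside trace time range "
            f"[{trace.time[0]}, {trace.time[-1]}]"
        )
    inner = (trace.time > t0) & (trace.time < t1)
    tt = np.concatenate([[t0], trace.time[inner], [t1]])
    yy = np.interp(tt, trace.time, trace.intensity)
    if baseline == "none":
        base = np.zeros_like(tt)
    elif baseline == "linear_endpoints":
        base = np.interp(tt, [t0, t1], [yy[0], yy[-1]])
    else:
        raise ValueError(f"unknown baseline {baseline!r}; use 'none' or 'linear_endpoints'")
    corrected = np.maximum(yy - base, 0.0)
    area = float(np.trapezoid(corrected, tt))
    return PeakArea(
        trace.peptide_id, trace.transition_id, trace.condition,
        trace.replicate_id, area, trace.dose_uM,
    )


def rollup_peptide(areas: list[PeakArea], method: str = "sum") -> PeakArea:
    """Collapse transition-level areas to one peptide-level area.

    All inputs must share peptide, condition and replicate. ``method`` is
    ``sum`` (default, common MRM practice) or ``mean``.
    """
    if not areas:
        raise ValueError("no transition areas to roll up")
    keys = {(a.peptide_id, a.condition, a.replicate_id, a.dose_uM) for a in areas}
    if len(keys) > 1:
        raise ValueError(f"mixed peptide/condition/replicate in rollup: {sorted(map(str, keys))}")
    values = [a.area for a in areas]
    if method == "sum":
        total = float(np.sum(values))
    elif method == "mean":
        total = float(np.mean(values))
    else:
        raise ValueError(f"unknown rollup method {method!r}")
    a0 = areas[0]
    return PeakArea(a0.peptide_id, "peptide", a0.condition, a0.replicate_id, total, a0.dose_uM)


def rollup_table(df: pd.DataFrame, method: str = "sum") -> pd.DataFrame:
    """Vectorised rollup of a long-form area table to peptide level."""
    agg = "sum" if method == "sum" else "mean"
    grouped = (
        df.groupby(["peptide_id", "condition", "dose_uM", "replicate_id"], dropna=False)["area"]
        .agg(agg)
        .reset_index()
    )
    grouped["transition_id"] = "peptide"
    return grouped[AREA_COLUMNS]


# ---------------------------------------------------------------------------
# LiP selection and fold changes


def floor_zero_areas(df: pd.DataFrame) -> pd.DataFrame:
    """Replace zero areas by half the smallest positive area (logged)."""
    if (df["area"] < 0).any():
        raise ValueError("negative peak areas in table")
    zeros = df["area"] == 0
    if zeros.any():
        positive = df.loc[df["area"] > 0, "area"]
        if positive.empty:
            raise ValueError("all areas are zero; nothing to floor against")
        floor = positive.min() / 2.0
        log.warning("floored %d zero areas at %.4g", int(zeros.sum()), floor)
        df = df.copy()
        df.loc[zeros, "area"] = floor
    return df


def _welch(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    import warnings

    with warnings.catch_warnings():
        # degenerate (all-identical) groups give a nan p-value; treated as 1
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def select_lip_peptides(df: pd.DataFrame, alpha: float = 0.05) -> list[LiPSelection]:
    """Identify subtilisin-sensitive (LiP) peptides.

    Per peptide, a one-sided Welch t-test on log2 areas tests whether the
    double-digest vehicle areas are lower than the trypsin-only control areas;
    a peptide is LiP when p <= alpha and the mean double-digest/trypsin-only
    ratio is below 1. Expects a peptide-level table (see :func:`rollup_table`).
    """
    df = floor_zero_areas(df)
    out = []
    for pid, sub in df.groupby("peptide_id", sort=True):
        tryp = sub.loc[sub["condition"] == TRYPSIN_ONLY, "area"].to_numpy(float)
        veh = sub.loc[sub["condition"] == DD_VEHICLE, "area"].to_numpy(float)
        if len(tryp) < 2 or len(veh) < 2:
            raise ValueError(
                f"peptide {pid}: need >= 2 replicates in both control conditions"
            )
        ratio = float(np.mean(veh) / np.mean(tryp))
        p = _welch(np.log2(veh), np.log2(tryp), alternative="less")
        out.append(LiPSelection(str(pid), bool(p <= alpha and ratio < 1.0), p, ratio))
    return out


def fold_change(df: pd.DataFrame, peptide_id: str, dose: float) -> FoldChange:
    """Ligand-over-vehicle fold change within the double-digest condition.

    fc = mean(area | dose) / mean(area | vehicle), means over replicates;
    p-value from a two-sided Welch t-test on log2 areas.
    """
    df = floor_zero_areas(df)
    sub = df[df["peptide_id"] == peptide_id]
    veh = sub.loc[sub["condition"] == DD_VEHICLE, "area"].to_numpy(float)
    dosed = sub.loc[
        (sub["condition"] == DD_DOSE) & (sub["dose_uM"] == dose), "area"
    ].to_numpy(float)
    if len(veh) == 0 or len(dosed) == 0:
        raise KeyError(
            f"peptide {peptide_id}: missing areas for dose {dose} or vehicle"
        )
    mean_veh = float(np.mean(veh))
    if mean_veh == 0:
        raise ZeroDivisionError(f"peptide {peptide_id}: vehicle mean area is zero")
    fc = float(np.mean(dosed)) / mean_veh
    if len(veh) >= 2 and len(dosed) >= 2:
        p = _welch(np.log2(dosed), np.log2(veh), alternative="two-sided")
    else:
        p = 1.0
    return FoldChange(peptide_id, dose, fc, p)


def fold_changes(df: pd.DataFrame) -> list[FoldChange]:
    """Fold change of every peptide at every dose present in the table."""
    df = floor_zero_areas(df)
    doses = sorted(df.loc[df["condition"] == DD_DOSE, "dose_uM"].dropna().unique())
    out = []
    for pid in sorted(df["peptide_id"].unique()):
        for dose in doses:
            out.append(fold_change(df, pid, dose))
    return out


def call_protected(
    lip: list[LiPSelection],
    fcs: list[FoldChange],
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> set[str]:
    """Peptides carrying a ligand-protection signal.

    A peptide is called when it is LiP (only subtilisin-sensitive peptides
    report conformation) and at >= 1 dose its fold change is >= ``fc_min``
    with p <= ``alpha``.
    """
    lip_ids = {s.peptide_id for s in lip if s.is_lip}
    called = set()
    for fc in fcs:
        if fc.peptide_id in lip_ids and fc.fc >= fc_min and fc.p_value <= alpha:
            called.add(fc.peptide_id)
    return called


# ---------------------------------------------------------------------------
# region mapping


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended 1-based inclusive intervals."""
    if not intervals:
        return []
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def map_regions(
    peptide_intervals: list[tuple[int, int]], protein: ProteinRecord
) -> RegionReport:
    """Merge protected peptides into intervals and overlay the annotation track.

    Overlaps report the number of shared residues with each interval/loop/helix
    annotation; point annotations (kind ``residue``) are reported as hits when
    they fall inside a merged interval.
    """
    for start, end in peptide_intervals:
        if not (1 <= start <= end <= len(protein)):
            raise ValueError(
                f"peptide interval {start}-{end} outside protein {protein.id} "
                f"(length {len(protein)})"
            )
    merged = merge_intervals(list(peptide_intervals))
    overlaps = []
    residue_hits = []
    for iv in merged:
        for ann in protein.annotations:
            lo, hi = max(iv[0], ann.start), min(iv[1], ann.end)
            if lo > hi:
                continue
            if ann.kind is AnnotationKind.RESIDUE:
                residue_hits.append(ann.name)
            else:
                overlaps.append((iv, ann.name, hi - lo + 1))
    return RegionReport(tuple(merged), tuple(overlaps), tuple(residue_hits))


def region_report_markdown(
    report: RegionReport,
    fcs: list[FoldChange] | None = None,
    lip: list[LiPSelection] | None = None,
) -> str:
    """Human-readable markdown summary of a region report."""
    lines = ["| interval | annotation | overlap (residues) |", "|---|---|---|"]
    for iv, name, n in report.overlaps:
        lines.append(f"| {iv[0]}-{iv[1]} | {name} | {n} |")
    if report.residue_hits:
        lines.append("")
        lines.append("Residue hits: " + ", ".join(report.residue_hits))
    if fcs:
        lines.append("")
        lines.append("| peptide | dose (uM) | FC | p |")
        lines.append("|---|---|---|---|")
        for fc in fcs:
            lines.append(f"| {fc.peptide_id} | {fc.dose:g} | {fc.fc:.2f} | {fc.p_value:.3g} |")
    return "\n".join(lines) + "\n"
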