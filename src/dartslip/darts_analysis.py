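"""DARTS protection scoring, replicate intersection, and target ranking.

Drug Affinity Responsive Target Stability (DARTS) reads out ligand binding as
protection from limited proteolysis: a bound target retains more of its
identification score after digestion than unbound proteins. Each replicate
carries an undigested (positive) control, a vehicle-digested (negative)
control, and one digested sample per ligand dose. Protection of a protein at a
dose is the score recovery normalised between the two controls::

    protection % = 100 * (S_dose - S_vehicle) / (S_undigested - S_vehicle)

clipped to [0, 100]. Candidate targets are proteins protected in every
replicate; they are ranked by mean protection. The module also normalises the
densitometric validation series (band / loading control vs dose).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

UNDIGESTED = "undigested_control"
VEHICLE = "digested_vehicle"


class DegenerateControlError(ValueError):
    """Undigested control score does not exceed the vehicle-digested score."""


@dataclass
class IdentificationTable:
    """Protein identification scores for one replicate across conditions.

    ``undigested`` and ``vehicle`` map protein id -> score; ``doses`` maps
    dose (µM) -> {protein id -> score}. Scores are Mascot-like, non-negative;
    spectral counts may be used interchangeably (the protection formula is a
    pure ratio).
    """

    replicate_id: str
    undigested: dict[str, float]
    vehicle: dict[str, float]
    doses: dict[float, dict[str, float]]

    def __post_init__(self) -> None:
        for cond, scores in [("undigested", self.undigested), ("vehicle", self.vehicle)] + [
            (f"dose {d}", s) for d, s in self.doses.items()
        ]:
            for pid, s in scores.items():
                if s < 0:
                    raise ValueError(
                        f"replicate {self.replicate_id}, {cond}: negative score for {pid}"
                    )
        if not self.doses:
            raise ValueError(f"replicate {self.replicate_id}: no dose condition present")


@dataclass(frozen=True)
class ProtectionRecord:
    protein_id: str
    dose: float
    protection: float  # percent, clipped to [0, 100]
    replicate_id: str


@dataclass(frozen=True)
class TargetRanking:
    protein_id: str
    mean_protection: float
    n_replicates_protected: int
    doses_protected: tuple[float, ...]
    mean_by_dose: tuple[tuple[float, float], ...] = ()  # (dose, mean %) pairs


@dataclass
class DensitometrySeries:
    lanes: list[str]
    band_intensity: list[float]
    loading_intensity: list[float]

    def __post_init__(self) -> None:
        if len(self.band_intensity) != len(self.loading_intensity):
            raise ValueError("band and loading vectors differ in length")


def compute_protection(
    table: IdentificationTable, protein_id: str, dose: float
) -> ProtectionRecord:
    """Protection percentage of one protein at one dose within one replicate.

    A protein absent from the dose condition scores 0 (absence of
    identification is informative in DARTS); absence from either control is an
    error, as the normalisation is then undefined.
    """
    try:
        s_undig = table.undigested[protein_id]
        s_veh = table.vehicle[protein_id]
    except KeyError as exc:
        raise KeyError(
            f"protein {protein_id} missing from control condition {exc} "
            f"in replicate {table.replicate_id}"
        ) from None
    if s_undig <= s_veh:
        raise DegenerateControlError(
            f"replicate {table.replicate_id}, protein {protein_id}: undigested score "
            f"{s_undig} <= vehicle score {s_veh}; protection undefined"
        )
    if dose not in table.doses:
        raise KeyError(f"dose {dose} not present in replicate {table.replicate_id}")
    s_dose = table.doses[dose].get(protein_id, 0.0)
    raw = 100.0 * (s_dose - s_veh) / (s_undig - s_veh)
    return ProtectionRecord(protein_id, dose, min(100.0, max(0.0, raw)), table.replicate_id)


def protection_records(
    table: IdentificationTable, skip_degenerate: bool = True
) -> list[ProtectionRecord]:
    """All (protein, dose) protection records for one replicate.

    Proteins with degenerate controls (undigested <= vehicle) are skipped with
    a warning when ``skip_degenerate``; otherwise the error propagates.
    """
    out = []
    for pid in table.undigested:
        if pid not in table.vehicle:
            continue
        for dose in table.doses:
            try:
                out.append(compute_protection(table, pid, dose))
            except DegenerateControlError:
                if not skip_degenerate:
                    raise
                log.warning(
                    "replicate %s: degenerate controls for %s; skipped", table.replicate_id, pid
                )
                break
    return out


def _protected_sets(
    tables: list[IdentificationTable], floor: float
) -> dict[str, set[str]]:
    """Per replicate, the set of proteins with protection > floor at >= 1 dose."""
    sets: dict[str, set[str]] = {}
    for table in tables:
        protected = {
            rec.protein_id
            for rec in protection_records(table)
            if rec.protection > floor
        }
        sets[table.replicate_id] = protected
    return sets


def intersect_replicates(
    tables: list[IdentificationTable], floor: float = 0.0
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Proteins protected (above ``floor`` percent, any dose) in every replicate.

    Returns ``(intersection, venn)`` where ``venn`` maps each non-empty subset
    of replicate ids to the number of proteins protected in exactly that
    subset. Venn cell counts therefore sum to the size of the union.
    """
    if len(tables) < 2:
        raise ValueError("replicate intersection needs >= 2 replicates")
    sets = _protected_sets(tables, floor)
    union = set().union(*sets.values())
    venn: dict[frozenset[str], int] = {}
    for pid in union:
        cell = frozenset(rid for rid, s in sets.items() if pid in s)
        venn[cell] = venn.get(cell, 0) + 1
    intersection = set.intersection(*sets.values()) if sets else set()
    return intersection, venn


def rank_targets(
    records: list[ProtectionRecord], intersection: set[str]
) -> list[TargetRanking]:
    """Rank intersection proteins by mean protection across replicates and doses.

    Ties break by number of protected replicates, then protein id
    (lexicographic) for determinism.
    """
    if not intersection:
        log.warning("empty intersection; no targets to rank")
        return []
    by_protein: dict[str, list[ProtectionRecord]] = {}
    for rec in records:
        if rec.protein_id in intersection:
            by_protein.setdefault(rec.protein_id, []).append(rec)
    rankings = []
    for pid, recs in by_protein.items():
        mean_prot = float(np.mean([r.protection for r in recs]))
        reps_protected = len({r.replicate_id for r in recs if r.protection > 0})
        doses_protected = tuple(sorted({r.dose for r in recs if r.protection > 0}))
        doses = sorted({r.dose for r in recs})
        mean_by_dose = tuple(
            (d, float(np.mean([r.protection for r in recs if r.dose == d]))) for d in doses
        )
        rankings.append(
            TargetRanking(pid, mean_prot, reps_protected, doses_protected, mean_by_dose)
        )
    rankings.sort(key=lambda t: (-t.mean_protection, -t.n_replicates_protected, t.protein_id))
    return rankings


def densitometry_trend(
    series: DensitometrySeries,
    doses: list[float],
    decrease_tolerance: float = 0.05,
) -> tuple[list[float], bool]:
    """Loading-normalised band intensities and a dose-monotonicity flag.

    The flag is true iff Spearman rho between dose and normalised intensity is
    positive and no step decreases by more than ``decrease_tolerance``
    (relative). Scale-invariant in both intensity vectors.
    """
    if len(doses) != len(series.band_intensity):
        raise ValueError("doses and intensities differ in length")
    for i, v in enumerate(series.loading_intensity):
        if v <= 0:
            raise ZeroDivisionError(f"non-positive loading intensity at lane {i}")
    normalized = [b / l for b, l in zip(series.band_intensity, series.loading_intensity)]
    order = np.argsort(doses, kind="stable")
    sorted_norm = np.asarray(normalized)[order]
    rho = stats.spearmanr(np.asarray(doses)[order], sorted_norm).statistic
    steps_ok = all(
        later >= earlier * (1.0 - decrease_tolerance)
        for earlier, later in zip(sorted_norm, sorted_norm[1:])
    )
    flag = bool(rho > 0 and steps_ok) if not math.isnan(rho) else False
    return normalized, flag
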