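"""Seeded synthetic datasets with planted ground truth for every pipeline stage.

The generators emulate the experimental designs the pipeline consumes:

* a random protein with realistic tryptic-site density and a structural
  annotation track modelled on brain glycogen phosphorylase (helix 2, cap
  loop, beta4/beta5 loop, tower helices, gate loop, N/C domains, key
  tyrosines);
* three-replicate DARTS identification-score tables with a concentration-
  dependent planted target over a low-protection background;
* four-condition t-LiP peak-area tables (trypsin-only, double-digest vehicle,
  double-digest + ligand at each dose) with multiplicative log-normal noise,
  planted subtilisin-sensitive peptides and ligand-protection fold changes;
* Gaussian chromatogram traces of known analytic area;
* four-parameter-logistic dose-response tables with known GI50.

Every generator is a pure function of its configuration (same seed, same
output) and returns the dataset together with a machine-readable truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .peptide_chem import (
    AnnotationInterval,
    AnnotationKind,
    ProteinRecord,
    TransitionConfig,
    digest_tryptic,
)
from .darts_analysis import IdentificationTable
from .tlip_mrm import AREA_COLUMNS, DD_DOSE, DD_VEHICLE, TRYPSIN_ONLY, ChromTrace

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# annotation track of the 5ikp-style phosphorylase fold, 1-based inclusive
PHOSPHORYLASE_FEATURES: tuple[tuple[str, int, int, str], ...] = (
    ("cap_loop", 41, 48, "loop"),
    ("helix_2", 49, 77, "helix"),
    ("beta4_beta5_loop", 180, 198, "loop"),
    ("tower_helices", 259, 278, "helix"),
    ("gate_loop", 279, 289, "loop"),
    ("N_domain", 22, 484, "domain"),
    ("C_domain", 485, 822, "domain"),
    ("Tyr75", 75, 75, "residue"),
    ("Tyr196", 196, 196, "residue"),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    Defaults reproduce the designs the pipeline is built for: 3 biological
    replicates, ligand doses 1 and 10 µM in t-LiP, a 5-fold area suppression
    of LiP peptides in the double digest, a 2-fold ligand-protection effect,
    10% multiplicative noise on MS areas, a DARTS dose series 1/10/100 µM with
    target protection rising 40/60/80% over a 0-10% background, and a growth
    curve with GI50 17 µM.
    """

    seed: int = 0
    protein_length: int = 900
    planted_protected_intervals: tuple[tuple[int, int], ...] = (
        (71, 78), (193, 206), (279, 290),
    )
    lip_suppression: float = 0.2
    protection_fc: float = 2.0
    noise_cv: float = 0.10
    n_replicates: int = 3
    doses: tuple[float, ...] = (1.0, 10.0)
    lip_fraction: float = 0.35  # fraction of non-planted peptides that are LiP decoys
    darts_doses: tuple[float, ...] = (1.0, 10.0, 100.0)
    darts_target_protection: tuple[float, ...] = (40.0, 60.0, 80.0)  # % per dose
    darts_background_protection: tuple[float, float] = (0.0, 10.0)  # uniform range %
    darts_survival: float = 0.25  # digestion survival fraction of the vehicle control
    gi50_true: float = 17.0  # µM
    hill_true: float = 1.0
    growth_noise_sd: float = 5.0  # percentage points on % growth

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if not (0 < self.lip_suppression <= 1):
            raise ValueError("lip_suppression must be in (0, 1]")
        if len(self.darts_target_protection) != len(self.darts_doses):
            raise ValueError("darts_target_protection must give one value per dose")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


# ---------------------------------------------------------------------------
# protein


def make_protein(cfg: SimulationConfig, protein_id: str = "SYN1") -> ProteinRecord:
    """Seeded random protein with ~11% K+R (tryptic-site density of real proteomes).

    When the protein is at least 823 residues long, the phosphorylase-fold
    annotation intervals are attached verbatim and the two key tyrosines are
    planted in the sequence; shorter proteins get the track scaled linearly.
    """
    if cfg.protein_length < 50:
        raise ValueError("protein_length must be >= 50")
    rng = np.random.default_rng(cfg.seed)
    probs = np.full(len(AMINO_ACIDS), 0.89 / 18.0)
    for aa in "KR":
        probs[AMINO_ACIDS.index(aa)] = 0.055
    letters = rng.choice(list(AMINO_ACIDS), size=cfg.protein_length, p=probs)
    if cfg.protein_length >= 823:
        letters[74] = "Y"
        letters[195] = "Y"
        features = PHOSPHORYLASE_FEATURES
    else:
        scale = cfg.protein_length / 823.0
        features = tuple(
            (name, max(1, round(s * scale)), max(1, round(e * scale)), kind)
            for name, s, e, kind in PHOSPHORYLASE_FEATURES
        )
    annotations = tuple(
        AnnotationInterval(name, s, e, AnnotationKind(kind)) for name, s, e, kind in features
    )
    return ProteinRecord(protein_id, "".join(letters), annotations)


# ---------------------------------------------------------------------------
# DARTS tables


def simulate_darts_tables(
    cfg: SimulationConfig,
    n_proteins: int = 300,
    target_ids: tuple[str, ...] = ("TARGET",),
) -> tuple[list[IdentificationTable], dict]:
    """Replicate identification-score tables with a planted protected target.

    Per replicate, undigested scores are log-normal; vehicle scores are the
    undigested scores times the digestion-survival fraction; dose scores
    interpolate from vehicle toward undigested so the planted protection is
    realised exactly, then pick up multiplicative log-normal noise (the
    controls stay noise-free so that zero noise reproduces the planted
    percentages exactly).
    """
    background_ids = [f"P{i:04d}" for i in range(n_proteins - len(target_ids))]
    all_ids = list(target_ids) + background_ids
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate protein ids")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.darts_background_protection
    tables = []
    for r in range(cfg.n_replicates):
        undig = rng.lognormal(mean=math.log(1000.0), sigma=0.5, size=len(all_ids))
        veh = undig * cfg.darts_survival
        doses: dict[float, dict[str, float]] = {}
        for k, dose in enumerate(cfg.darts_doses):
            planted = np.where(
                np.isin(all_ids, list(target_ids)),
                cfg.darts_target_protection[k],
                rng.uniform(lo, hi, size=len(all_ids)),
            )
            s_dose = veh + planted / 100.0 * (undig - veh)
            s_dose = s_dose * _lognormal_noise(rng, cfg.noise_cv, len(all_ids))
            doses[dose] = dict(zip(all_ids, s_dose.tolist()))
        tables.append(
            IdentificationTable(
                replicate_id=f"rep{r + 1}",
                undigested=dict(zip(all_ids, undig.tolist())),
                vehicle=dict(zip(all_ids, veh.tolist())),
                doses=doses,
            )
        )
    truth = {
        "target_ids": list(target_ids),
        "target_protection_by_dose": dict(
            zip(map(str, cfg.darts_doses), cfg.darts_target_protection)
        ),
        "background_protection_range": list(cfg.darts_background_protection),
        "n_proteins": n_proteins,
        "n_replicates": cfg.n_replicates,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# t-LiP areas


def _snap_to_peptide(
    interval: tuple[int, int], peptides: list
) -> tuple[int, int]:
    """Snap a planted interval to the nearest monitored tryptic peptide.

    The peptide with maximal overlap wins; when no monitored peptide overlaps
    (the interval falls entirely in peptides outside the MRM length bounds),
    the closest one by residue distance is used instead, so the realized truth
    can shift relative to the requested interval — the truth record is
    authoritative.
    """
    if not peptides:
        raise ValueError(
            f"planted interval {interval[0]}-{interval[1]}: protein has no "
            "monitored tryptic peptide to snap to"
        )
    best, best_key = None, None
    for pep in peptides:
        ov = min(interval[1], pep.end) - max(interval[0], pep.start) + 1
        # most overlap first (negative key), then smallest gap, then earliest start
        if ov > 0:
            key = (-ov, 0, pep.start)
        else:
            gap = max(pep.start - interval[1], interval[0] - pep.end)
            key = (0, gap, pep.start)
        if best_key is None or key < best_key:
            best, best_key = pep, key
    return (best.start, best.end)


def simulate_tlip_areas(
    cfg: SimulationConfig,
    protein: ProteinRecord,
    transition_config: TransitionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Peptide-level MRM area table for the four-condition t-LiP design.

    The monitored peptides are the fully tryptic, 0-missed-cleavage peptides
    within the MRM length bounds. Each planted interval snaps to the nearest
    monitored peptide (maximal overlap, then distance); that peptide becomes LiP (double-digest area
    = trypsin-only area x ``lip_suppression``) and ligand-protected (dose area
    further multiplied by ``protection_fc``). A configurable fraction of the
    remaining peptides are LiP decoys: suppressed but not protected. All areas
    carry multiplicative log-normal noise of CV ``noise_cv``.

    Returns the long-form area table and a truth record listing the snapped
    intervals and planted/decoy peptide ids.
    """
    tc = transition_config or TransitionConfig()
    monitored = [
        p
        for p in digest_tryptic(protein, max_missed=0)
        if tc.min_len <= len(p) <= tc.max_len
    ]
    if not monitored:
        raise ValueError("no monitored peptides; protein too short for the MRM bounds")
    snapped = [_snap_to_peptide(iv, monitored) for iv in cfg.planted_protected_intervals]
    planted_ids = {f"{s}-{e}" for s, e in snapped}
    rng = np.random.default_rng(cfg.seed + 1)
    others = [p for p in monitored if f"{p.start}-{p.end}" not in planted_ids]
    n_decoys = int(round(cfg.lip_fraction * len(others)))
    decoy_idx = rng.choice(len(others), size=n_decoys, replace=False) if n_decoys else []
    decoy_ids = {f"{others[i].start}-{others[i].end}" for i in decoy_idx}

    rows = []
    base = rng.lognormal(mean=math.log(1e5), sigma=0.5, size=len(monitored))
    for pep, b in zip(monitored, base):
        pid = f"{pep.start}-{pep.end}"
        is_lip = pid in planted_ids or pid in decoy_ids
        is_protected = pid in planted_ids
        for r in range(cfg.n_replicates):
            rep = f"rep{r + 1}"
            noise = _lognormal_noise(rng, cfg.noise_cv, 2 + len(cfg.doses))
            rows.append((pid, "peptide", TRYPSIN_ONLY, float("nan"), rep, b * noise[0]))
            dd = b * (cfg.lip_suppression if is_lip else 1.0)
            rows.append((pid, "peptide", DD_VEHICLE, float("nan"), rep, dd * noise[1]))
            for k, dose in enumerate(cfg.doses):
                dosed = dd * (cfg.protection_fc if is_protected else 1.0)
                rows.append((pid, "peptide", DD_DOSE, dose, rep, dosed * noise[2 + k]))
    df = pd.DataFrame(rows, columns=AREA_COLUMNS)
    truth = {
        "planted_intervals": [list(iv) for iv in cfg.planted_protected_intervals],
        "snapped_intervals": sorted([list(iv) for iv in set(snapped)]),
        "planted_peptide_ids": sorted(planted_ids),
        "decoy_lip_peptide_ids": sorted(decoy_ids),
        "protection_fc": cfg.protection_fc,
        "lip_suppression": cfg.lip_suppression,
        "doses_uM": list(cfg.doses),
    }
    return df, truth


def render_chromatogram(
    area: float,
    rt: float = 5.0,
    width: float = 0.1,
    dt: float = 0.005,
    peptide_id: str = "pep",
    transition_id: str = "t1",
    condition: str = TRYPSIN_ONLY,
    replicate_id: str = "rep1",
    dose_uM: float = float("nan"),
) -> ChromTrace:
    """Gaussian peak of known analytic ``area`` (intensity·min) on a regular grid.

    ``rt`` and ``width`` (the Gaussian sigma) are in minutes; the grid spans
    rt ± 6 sigma at spacing ``dt`` so the truncation error is negligible
    relative to the 1% integration tolerance the pipeline targets.
    """
    if area < 0 or width <= 0 or dt <= 0:
        raise ValueError("area must be >= 0, width and dt > 0")
    t = np.arange(rt - 6 * width, rt + 6 * width + dt / 2, dt)
    intensity = area / (width * math.sqrt(2 * math.pi)) * np.exp(
        -((t - rt) ** 2) / (2 * width * width)
    )
    return ChromTrace(peptide_id, transition_id, condition, replicate_id, t, intensity, dose_uM)


# ---------------------------------------------------------------------------
# dose-response


def simulate_dose_response(
    cfg: SimulationConfig,
    concentrations: tuple[float, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Viability table (T, T0, C per concentration) from a known 4PL growth curve.

    %-growth values come from a four-parameter logistic with top 100, bottom 0,
    midpoint ``gi50_true`` and slope ``hill_true``, plus Gaussian noise of
    ``growth_noise_sd`` percentage points; they are converted back to raw
    signals with fixed T0 and C so that the %-growth formula recovers them.
    """
    if concentrations is None:
        concentrations = tuple(np.geomspace(0.1, 200.0, 8))
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not (conc.min() < cfg.gi50_true < conc.max()):
        raise ValueError("doses must span gi50_true")
    rng = np.random.default_rng(cfg.seed + 2)
    growth = 100.0 / (1.0 + (conc / cfg.gi50_true) ** cfg.hill_true)
    growth = growth + rng.normal(0.0, cfg.growth_noise_sd, size=len(conc))
    T0, C = 0.2, 1.0
    T = T0 + growth / 100.0 * (C - T0)
    df = pd.DataFrame(
        {
            "concentration_uM": conc,
            "T": T,
            "T0": T0,
            "C": C,
            "replicate_id": "rep1",
        }
    )
    truth = {"gi50_true_uM": cfg.gi50_true, "hill_true": cfg.hill_true,
             "top": 100.0, "bottom": 0.0}
    return df, truth
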