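"""File formats: FASTA, annotation tracks, score/area/dose-response tables, reports.

All residue coordinates in every file are 1-based inclusive. Tables are plain
TSV/CSV with the column schemas declared by the consuming modules; reports are
emitted as JSON plus a human-readable markdown summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .darts_analysis import UNDIGESTED, VEHICLE, IdentificationTable, TargetRanking
from .peptide_chem import (
    AnnotationInterval,
    AnnotationKind,
    ProteinRecord,
    TransitionCandidate,
)
from .tlip_mrm import AREA_COLUMNS, DD_DOSE, DD_VEHICLE, TRYPSIN_ONLY, ChromTrace


class SchemaError(ValueError):
    """An input file does not match its declared schema."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read single- or multi-record FASTA; id is the first token of the header."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.split()[0]
        if pid in seen:
            raise SchemaError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(rec.seq).upper()))
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, proteins: list[ProteinRecord]) -> None:
    recs = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation track


def read_annotations(path: str | Path) -> list[AnnotationInterval]:
    """TSV with columns name, start, end, kind (coordinates 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "start", "end", "kind"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: annotation track needs columns {sorted(required)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                AnnotationInterval(
                    str(row["name"]), int(row["start"]), int(row["end"]),
                    AnnotationKind(str(row["kind"])),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}, line {i + 2}: {exc}") from None
    return out


def write_annotations(path: str | Path, annotations: list[AnnotationInterval]) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("name\tstart\tend\tkind\n")
        for a in annotations:
            fh.write(f"{a.name}\t{a.start}\t{a.end}\t{a.kind.value}\n")


# ---------------------------------------------------------------------------
# DARTS identification tables


_DARTS_CONDITIONS = {UNDIGESTED, VEHICLE, "digested_dose"}


def read_identification_tables(path: str | Path) -> list[IdentificationTable]:
    """TSV with columns replicate_id, condition, dose_uM, protein_id, score."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"replicate_id", "condition", "dose_uM", "protein_id", "score"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: identification table needs columns {sorted(required)}")
    bad = set(df["condition"].unique()) - _DARTS_CONDITIONS
    if bad:
        raise SchemaError(
            f"{path}: unknown condition label(s) {sorted(bad)}; "
            f"expected {sorted(_DARTS_CONDITIONS)}"
        )
    tables = []
    for rid, sub in df.groupby("replicate_id", sort=True):
        undig = dict(
            zip(
                sub.loc[sub["condition"] == UNDIGESTED, "protein_id"],
                sub.loc[sub["condition"] == UNDIGESTED, "score"].astype(float),
            )
        )
        veh = dict(
            zip(
                sub.loc[sub["condition"] == VEHICLE, "protein_id"],
                sub.loc[sub["condition"] == VEHICLE, "score"].astype(float),
            )
        )
        doses = {}
        dosed = sub[sub["condition"] == "digested_dose"]
        for dose, dsub in dosed.groupby("dose_uM"):
            doses[float(dose)] = dict(
                zip(dsub["protein_id"], dsub["score"].astype(float))
            )
        tables.append(IdentificationTable(str(rid), undig, veh, doses))
    return tables


def write_identification_tables(
    path: str | Path, tables: list[IdentificationTable]
) -> None:
    rows = []
    for t in tables:
        for pid, s in t.undigested.items():
            rows.append((t.replicate_id, UNDIGESTED, "", pid, s))
        for pid, s in t.vehicle.items():
            rows.append((t.replicate_id, VEHICLE, "", pid, s))
        for dose, scores in t.doses.items():
            for pid, s in scores.items():
                rows.append((t.replicate_id, "digested_dose", dose, pid, s))
    pd.DataFrame(
        rows, columns=["replicate_id", "condition", "dose_uM", "protein_id", "score"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peak-area and chromatogram tables


_TLIP_CONDITIONS = {TRYPSIN_ONLY, DD_VEHICLE, DD_DOSE}


def read_area_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not set(AREA_COLUMNS).issubset(df.columns):
        raise SchemaError(f"{path}: area table needs columns {AREA_COLUMNS}")
    bad = set(df["condition"].unique()) - _TLIP_CONDITIONS
    if bad:
        raise SchemaError(
            f"{path}: unknown condition label(s) {sorted(bad)}; "
            f"expected {sorted(_TLIP_CONDITIONS)}"
        )
    df["peptide_id"] = df["peptide_id"].astype(str)
    return df[AREA_COLUMNS]


def write_area_table(path: str | Path, df: pd.DataFrame) -> None:
    df[AREA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chromatograms(path: str | Path) -> list[ChromTrace]:
    """Long-form trace TSV: peptide_id, transition_id, condition, dose_uM,
    replicate_id, time_min, intensity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "peptide_id", "transition_id", "condition", "dose_uM",
        "replicate_id", "time_min", "intensity",
    }
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: chromatogram table needs columns {sorted(required)}")
    traces = []
    keys = ["peptide_id", "transition_id", "condition", "dose_uM", "replicate_id"]
    for key, sub in df.groupby(keys, dropna=False, sort=True):
        sub = sub.sort_values("time_min")
        traces.append(
            ChromTrace(
                str(key[0]), str(key[1]), str(key[2]), str(key[4]),
                sub["time_min"].to_numpy(float), sub["intensity"].to_numpy(float),
                float(key[3]),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# dose-response


def read_dose_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"concentration_uM", "T", "T0", "C"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: dose-response table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# outputs


def write_transitions(path: str | Path, transitions: list[TransitionCandidate]) -> None:
    """Transition list TSV, one row per (precursor, fragment) pair."""
    rows = []
    for t in transitions:
        for frag in t.fragments:
            rows.append(
                (
                    t.peptide.protein_id, t.peptide.sequence, t.peptide.start,
                    t.peptide.end, round(t.precursor_mz, 5), t.precursor_charge,
                    frag.series, frag.index, frag.charge, round(frag.mz, 5),
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "protein_id", "peptide", "start", "end", "precursor_mz", "precursor_z",
            "fragment_series", "fragment_index", "fragment_z", "fragment_mz",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_json_report(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def ranking_to_json(
    rankings: list[TargetRanking], venn: dict[frozenset[str], int]
) -> dict:
    return {
        "ranking": [asdict(r) for r in rankings],
        "venn": {"+".join(sorted(cell)): count for cell, count in venn.items()},
    }
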