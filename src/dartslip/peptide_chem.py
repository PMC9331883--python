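"""In-silico proteolysis, peptide/fragment mass arithmetic, and MRM transition design.

This module provides the peptide-level groundwork for a targeted limited-proteolysis
(t-LiP-MRM) workflow: tryptic and semi-tryptic digestion of a protein sequence,
monoisotopic/average peptide masses with the usual fixed/variable modifications,
b/y fragment-ion m/z values, and a deterministic selection of MRM transition
candidates for the fully tryptic peptides that map a protein.

Conventions
-----------
* Residue coordinates are 1-based and inclusive throughout ("peptide 71-78").
* Trypsin cleaves C-terminal to K or R, suppressed when the next residue is P.
* Protein N/C termini count as tryptic termini, so "fully tryptic" includes
  protein-terminal peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

# Standard amino-acid residue masses (Da), 5 decimals.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.05132, "A": 71.07880, "S": 87.07730, "P": 97.11518, "V": 99.13256,
    "T": 101.10388, "C": 103.14290, "L": 113.15764, "I": 113.15764, "N": 114.10264,
    "D": 115.08740, "Q": 128.12922, "K": 128.17408, "E": 129.11398, "M": 131.19606,
    "H": 137.13928, "F": 147.17386, "R": 156.18568, "Y": 163.17326, "W": 186.20990,
}

PROTON_MASS = 1.007276
WATER_MONO = 18.010565
WATER_AVG = 18.01528

#: Supported named modifications: name -> (target residue, monoisotopic delta Da)
MODIFICATIONS: dict[str, tuple[str, float]] = {
    "carbamidomethyl": ("C", 57.02146),
    "oxidation": ("M", 15.99491),
}

VALID_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASS)


class AlphabetError(ValueError):
    """A sequence contains a letter outside the 20 standard amino acids."""


class TerminalStatus(str, Enum):
    FULLY_TRYPTIC = "fully_tryptic"
    SEMI_TRYPTIC = "semi_tryptic"
    NON_TRYPTIC = "non_tryptic"


class AnnotationKind(str, Enum):
    DOMAIN = "domain"
    HELIX = "helix"
    LOOP = "loop"
    RESIDUE = "residue"


def validate_sequence(sequence: str, context: str = "sequence") -> None:
    """Raise :class:`AlphabetError` naming the first offending position."""
    if not sequence:
        raise AlphabetError(f"{context} is empty")
    for i, aa in enumerate(sequence, start=1):
        if aa not in VALID_RESIDUES:
            raise AlphabetError(
                f"{context} contains invalid residue {aa!r} at position {i} "
                "(B, J, O, U, X, Z and non-amino-acid letters are rejected)"
            )


@dataclass(frozen=True)
class AnnotationInterval:
    """A named structural feature on a protein, 1-based inclusive."""

    name: str
    start: int
    end: int
    kind: AnnotationKind = AnnotationKind.DOMAIN

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"annotation {self.name}: invalid interval {self.start}-{self.end}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier and structural annotation track."""

    id: str
    sequence: str
    annotations: tuple[AnnotationInterval, ...] = ()

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, context=f"protein {self.id}")
        for ann in self.annotations:
            if ann.end > len(self.sequence):
                raise ValueError(
                    f"annotation {ann.name} ({ann.start}-{ann.end}) exceeds "
                    f"protein {self.id} length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideSpecies:
    """A located sub-sequence of a protein with tryptic-terminus classification.

    ``mods`` holds (1-based position within the peptide, mass delta in Da) pairs.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    n_missed: int
    terminal_status: TerminalStatus
    mods: tuple[tuple[int, float], ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float


@dataclass(frozen=True)
class TransitionCandidate:
    peptide: PeptideSpecies
    precursor_mz: float
    precursor_charge: int
    fragments: tuple[FragmentIon, ...]
    score: float = 0.0


@dataclass(frozen=True)
class TransitionConfig:
    """Tunables for :func:`select_transitions`.

    Defaults reflect common targeted-proteomics practice: precursors at 2+/3+,
    peptide lengths 6-25, the top three high-index y ions above m/z 300.
    """

    min_len: int = 6
    max_len: int = 25
    charges: tuple[int, ...] = (2, 3)
    n_fragments: int = 3
    fragment_mz_min: float = 300.0
    exclude_residues: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# cleavage-site machinery


def _cleavage_sites(sequence: str) -> list[int]:
    """Positions i (1-based) such that trypsin cleaves between i and i+1.

    Cleavage after K/R unless the following residue is P.
    """
    sites = []
    for i in range(1, len(sequence)):  # i counts residues before the bond
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            sites.append(i)
    return sites


def is_tryptic_nterm(sequence: str, start: int) -> bool:
    """Whether a peptide starting at ``start`` (1-based) has a tryptic N-terminus."""
    if start == 1:
        return True
    return sequence[start - 2] in "KR" and sequence[start - 1] != "P"


def is_tryptic_cterm(sequence: str, end: int) -> bool:
    """Whether a peptide ending at ``end`` (1-based inclusive) has a tryptic C-terminus."""
    if end == len(sequence):
        return True
    return sequence[end - 1] in "KR" and sequence[end] != "P"


def count_missed(sequence: str, start: int, end: int) -> int:
    """Internal missed K/R cleavage sites in protein[start..end], proline rule honoured."""
    return sum(
        1
        for p in range(start, end)  # bond after residue p is internal iff p < end
        if sequence[p - 1] in "KR" and sequence[p] != "P"
    )


def classify_termini(sequence: str, start: int, end: int) -> TerminalStatus:
    n = is_tryptic_nterm(sequence, start)
    c = is_tryptic_cterm(sequence, end)
    if n and c:
        return TerminalStatus.FULLY_TRYPTIC
    if n or c:
        return TerminalStatus.SEMI_TRYPTIC
    return TerminalStatus.NON_TRYPTIC


def _make_peptide(protein: ProteinRecord, start: int, end: int) -> PeptideSpecies:
    seq = protein.sequence
    return PeptideSpecies(
        protein_id=protein.id,
        start=start,
        end=end,
        sequence=seq[start - 1 : end],
        n_missed=count_missed(seq, start, end),
        terminal_status=classify_termini(seq, start, end),
    )


# ---------------------------------------------------------------------------
# digestion


def digest_tryptic(protein: ProteinRecord, max_missed: int = 0) -> list[PeptideSpecies]:
    """Fully tryptic peptides of ``protein`` with at most ``max_missed`` missed cleavages.

    Peptides are located 1-based inclusive and returned ordered by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    boundaries = [0] + _cleavage_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            peptides.append(_make_peptide(protein, start, end))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def enumerate_semitryptic(
    protein: ProteinRecord, min_len: int, max_len: int
) -> list[PeptideSpecies]:
    """All semi-tryptic peptides (exactly one tryptic terminus) with length in bounds.

    Models a single subtilisin cut followed by complete trypsin digestion: one
    terminus is tryptic (or a protein terminus, which counts as tryptic), the
    other is not. Fully tryptic peptides are excluded.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    seq = protein.sequence
    out = []
    for start in range(1, len(seq) + 1):
        for end in range(start + min_len - 1, min(start + max_len - 1, len(seq)) + 1):
            if classify_termini(seq, start, end) is TerminalStatus.SEMI_TRYPTIC:
                out.append(_make_peptide(protein, start, end))
    out.sort(key=lambda p: (p.start, p.end))
    return out


# ---------------------------------------------------------------------------
# masses


def _residue_table(kind: str) -> tuple[dict[str, float], float]:
    if kind == "monoisotopic":
        return MONOISOTOPIC_RESIDUE_MASS, WATER_MONO
    if kind == "average":
        return AVERAGE_RESIDUE_MASS, WATER_AVG
    raise ValueError(f"unknown mass kind {kind!r}; use 'monoisotopic' or 'average'")


def peptide_mass(
    sequence: str,
    mods: Iterable[str] = (),
    kind: str = "monoisotopic",
) -> float:
    """Neutral peptide mass in Da.

    ``mods`` is a set of modification names applied to every matching residue:
    ``carbamidomethyl`` (fixed, +57.02146 on C) and ``oxidation`` (+15.99491 on M).
    """
    validate_sequence(sequence, context="peptide")
    table, water = _residue_table(kind)
    mass = sum(table[aa] for aa in sequence) + water
    for name in mods:
        try:
            target, delta = MODIFICATIONS[name]
        except KeyError:
            raise ValueError(
                f"unknown modification {name!r}; supported: {sorted(MODIFICATIONS)}"
            ) from None
        mass += delta * sequence.count(target)
    return mass


def protein_average_mass(sequence: str) -> float:
    """Average (chemical) molecular mass of an unmodified protein, in Da."""
    return peptide_mass(sequence, kind="average")


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """m/z of an ion carrying ``charge`` protons."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def _mod_deltas(peptide: PeptideSpecies) -> dict[int, float]:
    deltas: dict[int, float] = {}
    for pos, delta in peptide.mods:
        deltas[pos] = deltas.get(pos, 0.0) + delta
    return deltas


def peptide_species_mass(peptide: PeptideSpecies, kind: str = "monoisotopic") -> float:
    """Neutral mass of a located peptide including its positional modifications."""
    base = peptide_mass(peptide.sequence, kind=kind)
    return base + sum(delta for _, delta in peptide.mods)


def fragment_ions(peptide: PeptideSpecies, max_charge: int = 1) -> list[FragmentIon]:
    """b- and y-series fragment ions of ``peptide`` at charges 1..max_charge.

    Positional modifications are assigned to whichever fragment contains the
    modified residue.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("fragmentation needs peptide length >= 2")
    table, water = _residue_table("monoisotopic")
    deltas = _mod_deltas(peptide)
    prefix = [0.0]
    for i, aa in enumerate(seq, start=1):
        prefix.append(prefix[-1] + table[aa] + deltas.get(i, 0.0))
    total = prefix[-1]
    ions = []
    for z in range(1, max_charge + 1):
        for i in range(1, n):
            ions.append(FragmentIon("b", i, z, precursor_mz(prefix[i], z)))
        for j in range(1, n):
            ions.append(FragmentIon("y", j, z, precursor_mz(total - prefix[n - j] + water, z)))
    return ions


# ---------------------------------------------------------------------------
# transition selection


def select_transitions(
    protein: ProteinRecord, config: TransitionConfig | None = None
) -> list[TransitionCandidate]:
    """Deterministic MRM transition candidates for the fully tryptic peptides.

    Stand-in for a spectral-library lookup: peptides are the 0-missed-cleavage
    fully tryptic digest filtered by length and residue exclusion; fragments are
    the top-K singly charged y ions above the low-mass cutoff, taken from the
    high-index end (the most sequence-informative daughters).
    """
    cfg = config or TransitionConfig()
    if len(protein) < cfg.min_len:
        log.warning(
            "protein %s (length %d) shorter than minimum peptide length %d; "
            "no transitions generated", protein.id, len(protein), cfg.min_len,
        )
        return []
    out = []
    for pep in digest_tryptic(protein, max_missed=0):
        if not (cfg.min_len <= len(pep) <= cfg.max_len):
            continue
        if cfg.exclude_residues and set(pep.sequence) & cfg.exclude_residues:
            continue
        neutral = peptide_species_mass(pep)
        y_ions = [
            ion
            for ion in fragment_ions(pep, max_charge=1)
            if ion.series == "y" and ion.mz >= cfg.fragment_mz_min
        ]
        y_ions.sort(key=lambda ion: ion.index, reverse=True)
        chosen = tuple(y_ions[: cfg.n_fragments])
        for z in cfg.charges:
            out.append(
                TransitionCandidate(
                    peptide=pep,
                    precursor_mz=precursor_mz(neutral, z),
                    precursor_charge=z,
                    fragments=chosen,
                )
            )
    out.sort(key=lambda t: (t.peptide.start, t.peptide.end, t.precursor_charge))
    return out


def map_peptide(protein: ProteinRecord, peptide_sequence: str) -> list[tuple[int, int]]:
    """All occurrences of ``peptide_sequence`` in the protein, 1-based inclusive."""
    if not peptide_sequence:
        raise ValueError("empty query")
    hits = []
    pos = protein.sequence.find(peptide_sequence)
    while pos != -1:
        hits.append((pos + 1, pos + len(peptide_sequence)))
        pos = protein.sequence.find(peptide_sequence, pos + 1)
    return hits
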