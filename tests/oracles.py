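"""Independent brute-force oracles used by the test suite.

These re-derive expected results directly from first principles (exhaustive
substring enumeration, hand-summed masses) without touching the package's own
digestion or mass machinery, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Published monoisotopic residue masses, independent copy for hand-sums.
REFERENCE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
REFERENCE_WATER = 18.010565
REFERENCE_PROTON = 1.007276


def _nterm_tryptic(seq: str, start: int) -> bool:
    """1-based start; cleavage after K/R unless next residue is P."""
    return start == 1 or (seq[start - 2] in "KR" and seq[start - 1] != "P")


def _cterm_tryptic(seq: str, end: int) -> bool:
    return end == len(seq) or (seq[end - 1] in "KR" and seq[end] != "P")


def _missed(seq: str, start: int, end: int) -> int:
    return sum(
        1 for p in range(start, end) if seq[p - 1] in "KR" and seq[p] != "P"
    )


def brute_force_tryptic(seq: str, max_missed: int) -> set[tuple[int, int]]:
    """Every fully tryptic substring with <= max_missed internal cleavage sites."""
    out = set()
    for s in range(1, len(seq) + 1):
        for e in range(s, len(seq) + 1):
            if (
                _nterm_tryptic(seq, s)
                and _cterm_tryptic(seq, e)
                and _missed(seq, s, e) <= max_missed
            ):
                out.add((s, e))
    return out


def brute_force_semitryptic(seq: str, min_len: int, max_len: int) -> set[tuple[int, int]]:
    """Every substring in the length bounds with exactly one tryptic terminus."""
    out = set()
    for s in range(1, len(seq) + 1):
        for e in range(s, len(seq) + 1):
            if not (min_len <= e - s + 1 <= max_len):
                continue
            if _nterm_tryptic(seq, s) != _cterm_tryptic(seq, e):
                out.add((s, e))
    return out


def hand_mass(seq: str) -> float:
    """Plain sum over the independent residue-mass table plus water."""
    return sum(REFERENCE_MONO[a] for a in seq) + REFERENCE_WATER
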