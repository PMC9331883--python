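"""Digestion, mass arithmetic, fragmentation and transition selection."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as ptmass
from pyteomics import parser as ptparser

from dartslip import peptide_chem as pc
from dartslip import (
    ProteinRecord,
    TransitionConfig,
    digest_tryptic,
    enumerate_semitryptic,
    fragment_ions,
    map_peptide,
    peptide_mass,
    precursor_mz,
    select_transitions,
)

from .oracles import (
    AA20,
    REFERENCE_PROTON,
    brute_force_semitryptic,
    brute_force_tryptic,
    hand_mass,
)

sequences = st.text(alphabet=AA20, min_size=1, max_size=12)
peptides = st.text(alphabet=AA20, min_size=2, max_size=20)


def located(peps):
    return {(p.start, p.end) for p in peps}


class TestDigestTryptic:
    @pytest.mark.parametrize(
        "seq, max_missed, expected",
        [
            ("MAAA", 0, {(1, 4)}),  # no cleavage sites
            ("AKRPC", 1, {(1, 2), (1, 5), (3, 5)}),  # R|P suppressed
            ("KKK", 2, {(1, 1), (2, 2), (3, 3), (1, 2), (2, 3), (1, 3)}),
        ],
    )
    def test_known_digests(self, seq, max_missed, expected):
        peps = digest_tryptic(ProteinRecord("p", seq), max_missed)
        assert located(peps) == expected
        assert all(p.sequence == seq[p.start - 1 : p.end] for p in peps)
        assert [(p.start, p.end) for p in peps] == sorted((p.start, p.end) for p in peps)

    def test_missed_cleavage_counts(self):
        peps = {(p.start, p.end): p.n_missed for p in digest_tryptic(ProteinRecord("p", "AKRPC"), 1)}
        assert peps == {(1, 2): 0, (1, 5): 1, (3, 5): 0}

    @given(seq=sequences, max_missed=st.integers(0, 2))
    def test_matches_exhaustive_oracle(self, seq, max_missed):
        peps = digest_tryptic(ProteinRecord("p", seq), max_missed)
        assert located(peps) == brute_force_tryptic(seq, max_missed)

    @given(seq=st.text(alphabet=AA20, min_size=5, max_size=40))
    def test_zero_missed_tiles_protein(self, seq):
        peps = digest_tryptic(ProteinRecord("p", seq), 0)
        assert "".join(p.sequence for p in peps) == seq

    @given(seq=st.text(alphabet=AA20, min_size=3, max_size=25))
    def test_agrees_with_pyteomics_cleave(self, seq):
        ours = {p.sequence for p in digest_tryptic(ProteinRecord("p", seq), 2)}
        theirs = ptparser.cleave(seq, ptparser.expasy_rules["trypsin"], missed_cleavages=2)
        assert ours == set(theirs)

    def test_invalid_residue_names_position(self):
        with pytest.raises(pc.AlphabetError, match="position 3"):
            ProteinRecord("p", "AAXK")


class TestSemitryptic:
    def test_protein_termini_count_as_tryptic(self):
        # both termini of every length-<=2 substring of "KA" are tryptic
        assert enumerate_semitryptic(ProteinRecord("p", "KA"), 1, 2) == []

    @given(seq=sequences, bounds=st.tuples(st.integers(1, 4), st.integers(1, 8)))
    def test_matches_exhaustive_oracle(self, seq, bounds):
        lo, hi = min(bounds), max(bounds)
        peps = enumerate_semitryptic(ProteinRecord("p", seq), lo, hi)
        assert located(peps) == brute_force_semitryptic(seq, lo, hi)

    @given(seq=sequences)
    def test_disjoint_from_fully_tryptic(self, seq):
        semi = located(enumerate_semitryptic(ProteinRecord("p", seq), 1, len(seq)))
        full = located(digest_tryptic(ProteinRecord("p", seq), max_missed=len(seq)))
        assert not semi & full

    def test_min_len_beyond_protein_gives_empty(self):
        assert enumerate_semitryptic(ProteinRecord("p", "MK"), 5, 9) == []


class TestMasses:
    @pytest.mark.parametrize(
        "seq, expected",
        [("G", 75.03203), ("PEPTIDE", 799.35997)],
    )
    def test_hand_summed_masses(self, seq, expected):
        assert peptide_mass(seq) == pytest.approx(expected, abs=1e-4)
        assert peptide_mass(seq) == pytest.approx(hand_mass(seq), abs=1e-9)

    def test_fixed_carbamidomethyl_is_additive(self):
        assert peptide_mass("C", mods=["carbamidomethyl"]) == pytest.approx(
            peptide_mass("C") + 57.02146, abs=1e-9
        )

    def test_oxidation_applies_per_methionine(self):
        assert peptide_mass("MAMA", mods=["oxidation"]) == pytest.approx(
            peptide_mass("MAMA") + 2 * 15.99491, abs=1e-9
        )

    def test_unknown_modification_lists_supported(self):
        with pytest.raises(ValueError, match="carbamidomethyl"):
            peptide_mass("C", mods=["phospho-nonsense"])

    @given(seq=peptides, split=st.integers(1, 19))
    def test_mass_additivity(self, seq, split):
        split = min(split, len(seq) - 1)
        left, right = seq[:split], seq[split:]
        assert peptide_mass(seq) == pytest.approx(
            peptide_mass(left) + peptide_mass(right) - pc.WATER_MONO, abs=1e-9
        )

    @given(seq=peptides)
    def test_monoisotopic_matches_pyteomics(self, seq):
        assert peptide_mass(seq) == pytest.approx(
            ptmass.fast_mass(seq, charge=0), abs=2e-3
        )

    @pytest.mark.parametrize(
        "neutral, charge, expected",
        [(1000.0, 1, 1001.007276), (1000.0, 2, 501.007276), (799.35997, 2, 400.687261)],
    )
    def test_precursor_mz(self, neutral, charge, expected):
        assert precursor_mz(neutral, charge) == pytest.approx(expected, abs=1e-5)

    def test_precursor_mz_rejects_nonpositive_charge(self):
        with pytest.raises(ValueError):
            precursor_mz(1000.0, 0)


def _species(seq):
    return pc.PeptideSpecies("p", 1, len(seq), seq, 0, pc.TerminalStatus.FULLY_TRYPTIC)


class TestFragments:
    def test_dipeptide_ions(self):
        ions = {(i.series, i.index): i.mz for i in fragment_ions(_species("AG"), 1)}
        assert ions[("b", 1)] == pytest.approx(72.04439, abs=1e-4)
        assert ions[("y", 1)] == pytest.approx(76.03930, abs=1e-4)

    @given(seq=peptides)
    def test_by_complementarity(self, seq):
        pep = _species(seq)
        ions = {(i.series, i.index): i.mz for i in fragment_ions(pep, 1)}
        total = peptide_mass(seq)
        for i in range(1, len(seq)):
            assert ions[("b", i)] + ions[("y", len(seq) - i)] == pytest.approx(
                total + 2 * REFERENCE_PROTON, abs=1e-9
            )

    @given(seq=peptides)
    def test_largest_y_ion_definition(self, seq):
        # y_{n-1} at 1+ is the protonated peptide minus the N-terminal residue
        ions = {(i.series, i.index): i.mz for i in fragment_ions(_species(seq), 1)}
        expected = peptide_mass(seq) - hand_mass(seq[0]) + pc.WATER_MONO + REFERENCE_PROTON
        assert ions[("y", len(seq) - 1)] == pytest.approx(expected, abs=1e-9)

    def test_modification_assigned_to_containing_fragment(self):
        pep = pc.PeptideSpecies(
            "p", 1, 3, "ACK", 0, pc.TerminalStatus.FULLY_TRYPTIC, mods=((2, 57.02146),)
        )
        plain = {(i.series, i.index): i.mz for i in fragment_ions(_species("ACK"), 1)}
        mod = {(i.series, i.index): i.mz for i in fragment_ions(pep, 1)}
        assert mod[("b", 1)] == pytest.approx(plain[("b", 1)], abs=1e-9)  # before C
        assert mod[("b", 2)] == pytest.approx(plain[("b", 2)] + 57.02146, abs=1e-9)
        assert mod[("y", 1)] == pytest.approx(plain[("y", 1)], abs=1e-9)  # after C
        assert mod[("y", 2)] == pytest.approx(plain[("y", 2)] + 57.02146, abs=1e-9)


class TestTransitions:
    def test_consistent_with_digest(self, phospho_like_protein):
        cands = select_transitions(phospho_like_protein)
        expected = {
            (p.start, p.end)
            for p in digest_tryptic(phospho_like_protein, 0)
            if 6 <= len(p) <= 25
        }
        assert {(c.peptide.start, c.peptide.end) for c in cands} == expected
        assert all(c.precursor_charge in (2, 3) for c in cands)
        starts = [c.peptide.start for c in cands]
        assert starts == sorted(starts)

    def test_deterministic(self, phospho_like_protein):
        a = select_transitions(phospho_like_protein)
        b = select_transitions(phospho_like_protein)
        assert a == b

    def test_fragment_count_clamps(self):
        prot = ProteinRecord("p", "MAGKPEPTIDEK")
        cfg = TransitionConfig(min_len=4, n_fragments=50, fragment_mz_min=0.0)
        cands = select_transitions(prot, cfg)
        pep_len = {c.peptide.sequence: len(c.fragments) for c in cands}
        for seq, nfrag in pep_len.items():
            assert nfrag == len(seq) - 1

    def test_fragments_respect_mz_cutoff_and_rank(self, phospho_like_protein):
        for cand in select_transitions(phospho_like_protein)[:50]:
            idx = [f.index for f in cand.fragments]
            assert idx == sorted(idx, reverse=True)
            assert all(f.mz >= 300.0 for f in cand.fragments)

    def test_short_protein_yields_empty(self):
        assert select_transitions(ProteinRecord("p", "MAK")) == []


class TestMapPeptide:
    @pytest.mark.parametrize(
        "seq, query, expected",
        [
            ("GAGA", "GA", [(1, 2), (3, 4)]),
            ("GAGA", "GAGA", [(1, 4)]),
            ("GAGA", "W", []),
        ],
    )
    def test_occurrences(self, seq, query, expected):
        assert map_peptide(ProteinRecord("p", seq), query) == expected

    @given(data=st.data())
    def test_window_recovered(self, data):
        seq = data.draw(st.text(alphabet="ACDEFGHI", min_size=50, max_size=50))
        start = data.draw(st.integers(1, 45))
        window = seq[start - 1 : start + 5]
        hits = map_peptide(ProteinRecord("p", seq), window)
        assert (start, start + 5) in hits
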