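"""In-silico tryptic digestion and MRM transition design for a small protein.

Digests a toy sequence, shows the located fully tryptic peptides with their
missed-cleavage counts, and builds MRM transition candidates (2+/3+ precursors,
top y ions) for a seeded synthetic protein.
"""

from dartslip import (
    ProteinRecord,
    SimulationConfig,
    TransitionConfig,
    digest_tryptic,
    make_protein,
    peptide_mass,
    select_transitions,
)

protein = ProteinRecord("demo", "MAGKPEPTIDEKAAAGGGRWWK")
print(f"protein {protein.id}: {protein.sequence} ({len(protein)} residues)\n")

print("fully tryptic peptides (<=1 missed cleavage), 1-based inclusive:")
for pep in digest_tryptic(protein, max_missed=1):
    print(
        f"  {pep.start:>3}-{pep.end:<3} {pep.sequence:<20} "
        f"missed={pep.n_missed} mass={peptide_mass(pep.sequence):.4f} Da"
    )
# note K|P at position 4-5 suppresses cleavage: MAGKPEPTIDEK stays intact

big = make_protein(SimulationConfig(seed=0))
candidates = select_transitions(big, TransitionConfig())
print(f"\n{big.id}: {len(candidates)} transition candidates "
      f"({len({c.peptide.sequence for c in candidates})} peptides x 2 charge states)")
first = candidates[0]
print(f"first candidate: peptide {first.peptide.start}-{first.peptide.end} "
      f"{first.peptide.sequence}, precursor m/z {first.precursor_mz:.4f} "
      f"({first.precursor_charge}+)")
for frag in first.fragments:
    print(f"  daughter {frag.series}{frag.index} ({frag.charge}+): m/z {frag.mz:.4f}")
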