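# dartslip

Drug-target deconvolution by DARTS and targeted limited proteolysis
(t-LiP-MRM), with the supporting pharmacology, as a tested Python library.

## The problem

When a bioactive small molecule works but its protein target is unknown,
label-free proteomics can find the target by exploiting a simple fact: a bound
ligand stabilises its target against proteolysis.

* **DARTS** (Drug Affinity Responsive Target Stability) digests a native cell
  lysate — pre-incubated with the ligand at increasing concentrations — with a
  low-specificity protease. The target's identification score recovers with
  dose. With an undigested positive control `S_und` and a vehicle-digested
  negative control `S_veh`, protection at a dose is

  ```
  protection % = 100 · (S_dose − S_veh) / (S_und − S_veh),   clipped to [0, 100]
  ```

  Proteins protected in every replicate are intersected (Venn) and ranked by
  mean protection.

* **t-LiP-MRM** localises the binding site. Native protein is nicked by
  subtilisin (which cuts flexible, exposed regions), then fully digested by
  trypsin; the fully tryptic peptides are quantified by MRM. Peptides whose
  area drops in the double digest versus the trypsin-only control are
  subtilisin-sensitive ("LiP peptides"); a LiP peptide whose area recovers
  under ligand treatment (fold change `FC = mean(area|dose)/mean(area|vehicle)`
  ≥ 1.5, Welch p ≤ 0.05 on log2 areas) marks a region the ligand shields.
  Protected peptides are merged into intervals and intersected with a
  structural annotation track (helices, loops, key residues).

* **Pharmacology**: `% growth = 100·(T − T0)/(C − T0)` with a 4-parameter
  logistic fit read off at the 50% crossing (GI50); single-time-point PAMPA
  effective permeability `Pe = −ln(1 − C_A/C_eq)·V_D·V_A/((V_D+V_A)·A·t)`
  reported as −log Pe; blank-corrected ΔA340 kinetics for a coupled
  glycogenolysis assay; and `Kd = exp(ΔG/RT)` for docking energetics.

Everything upstream of these formulas (in-silico tryptic digestion with the
proline rule, peptide/fragment masses, MRM transition design, chromatographic
peak integration) is included, as is a synthetic-data module that generates
every input with planted ground truth so the whole pipeline is testable
end to end without raw MS data.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_tlip_region_mapping.py`:

```
planted intervals [[71, 78], [193, 206], [279, 290]] snapped to tryptic peptides [[74, 85], [188, 210], [279, 286]]
23/56 monitored peptides are subtilisin-sensitive (LiP)
ligand-protected peptides: ['188-210', '279-286', '74-85']

| interval | annotation | overlap (residues) |
|---|---|---|
| 74-85 | helix_2 | 4 |
| 74-85 | N_domain | 12 |
| 188-210 | beta4_beta5_loop | 11 |
| 188-210 | N_domain | 23 |
| 279-286 | gate_loop | 8 |
| 279-286 | N_domain | 8 |

Residue hits: Tyr75, Tyr196
```

The generator planted 2-fold ligand protection on three intervals of a
900-residue phosphorylase-like protein (10% CV, n = 3); the pipeline recovers
exactly those peptides and maps them onto the annotated dimer-interface
features (helix 2, the β4/β5 loop, the gate loop) — the readout a structural
biologist would use to reason about a binding interface. Similarly,
`02_darts_target_ranking.py` plants a target protected 40/60/80% across a
1/10/100 µM series among 300 background proteins and recovers it as the
unique rank-1 candidate, and `04_pharmacology.py` prints

```
true GI50 17.0 uM; fitted GI50 20.1 uM (hill 0.89, 95% CI 11.8-31.4 uM)
PAMPA: Pe = 6.02e-06 cm/s, -log Pe = 5.22 -> permeable (-log Pe < 6 is good permeability)
dG = -7.884 kcal/mol at 298 K -> Kd_pred = 1.652 uM
```

A thin CLI mirrors the library (`dartslip digest|darts|tlip|pharm|simulate`).

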