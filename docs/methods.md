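# Methods

This note documents the models implemented in `dartslip`, the defaults and why
they were chosen, what the synthetic-data generators emulate (and do not), and
the numerical choices that affect results.

## Peptide chemistry

**Cleavage model.** Trypsin cleaves C-terminal to K or R, suppressed when the
next residue is P (the classical "trypsin" rule used by common search
engines). Protein N- and C-termini count as tryptic termini, so a "fully
tryptic" peptide may be protein-terminal; a semi-tryptic peptide has exactly
one tryptic terminus (modelling one subtilisin cut plus complete trypsin
digestion). Missed cleavages are internal K/R sites honouring the proline
rule. All coordinates are 1-based inclusive.

**Masses.** Monoisotopic and average residue masses are hard-coded standard
tables (5 decimals); water = 18.010565 Da (monoisotopic), proton =
1.007276 Da. Named modifications: carbamidomethyl (+57.02146 Da on C, the
usual fixed alkylation) and oxidation (+15.99491 Da on M, variable, off by
default to keep candidate lists small). b ions are cumulative N-terminal
residue sums; y ions add water; m/z = (M + z·1.007276)/z. The test suite
cross-checks masses and cleavage against pyteomics, which is never used in
the implementation itself.

**Transition selection.** MRM candidates are the 0-missed-cleavage fully
tryptic peptides with length in [6, 25], precursors at 2+ and 3+, and the top
3 singly charged y ions with m/z ≥ 300 taken from the high-index end. These
are conventional targeted-proteomics heuristics — spectral-library resources
do not publish their ranking criteria — and every one of them is a
`TransitionConfig` field, not a constant. Selection is deterministic.

## DARTS analysis

Protection normalises the dose score between the two controls,
`100·(S_dose − S_veh)/(S_und − S_veh)`, clipped to [0, 100]. Both controls
enter the formula because a candidate must be judged against both the
fully-digested baseline and the undigested ceiling; clipping absorbs score
noise outside the physical range. A protein absent from a dose condition
scores 0 (non-identification is informative); absence from a control, or
`S_und ≤ S_veh`, makes the normalisation undefined and is an error (such
proteins are skipped with a warning in bulk processing). The formula is a
pure ratio, hence invariant under per-replicate rescaling, and works equally
with search-engine scores or spectral counts.

Replicate intersection keeps proteins protected above a configurable floor
(default 0%) at ≥ 1 dose in every replicate and reports the full Venn
partition. Ranking averages protection across replicates and doses
(per-dose means are also reported, since pooling conventions differ across
labs) with deterministic tie-breaks (replicate count, then protein id).
Densitometric validation divides band intensity by a loading-control
intensity; the dose-monotonicity flag requires Spearman ρ > 0 and no
relative step decrease above 5% (tolerance configurable).

## t-LiP-MRM analysis

Peak areas are trapezoidal integrals over a retention-time window, with an
optional linear-endpoints baseline; the background-corrected signal is floored
at zero pointwise before integration. Transition areas roll up to peptide
level by summation (mean available). Zero areas are imputed at half the
smallest positive area in the table (standard intensity-data flooring) with a
logged warning.

LiP selection uses a one-sided Welch t-test on log2 areas (double-digest
vehicle < trypsin-only) at α = 0.05 together with a mean ratio < 1; log2
stabilises the multiplicative variance of MS intensities. Fold changes are
ratios of replicate means (dose over vehicle within the double-digest arm)
with a two-sided Welch p-value. No multiple-testing correction is applied by
default — the readout is a targeted panel of tens of peptides, and the
protection call already requires the conjunction of four conditions — and
p-values are reported raw. A protected call requires: LiP, FC ≥ 1.5 and
p ≤ 0.05 at ≥ 1 dose. The FC threshold is a conventional effect-size guard,
exposed in the API.

Region mapping merges overlapping or bookended peptide intervals (so adjacent
tryptic peptides form one region), intersects them with the annotation track,
reports per-annotation overlap residue counts, and flags point annotations
(key residues) falling inside a protected region.

## Pharmacology

* **% growth** is exactly `100·(T − T0)/(C − T0)`; it may be negative (net
  cytotoxicity) or exceed 100. The only guard is `C ≠ T0`.
* **GI50**: least-squares 4PL `y = bottom + (top − bottom)/(1 + (c/mid)^hill)`
  with the GI50 read off where the fitted curve crosses 50% growth — the
  growth-assay convention, which coincides with the midpoint only when
  top/bottom are 100/0. `fit_ok` requires a decreasing curve whose 50%
  crossing lies inside the tested range. Confidence intervals come from a
  seeded parametric bootstrap (default 500 refits on data resampled from the
  fitted curve plus the residual SD). A log-linear interpolation fallback
  estimator is provided.
* **PAMPA**: the two-compartment single-time-point model without a
  donor-depletion sampling term, `C_eq = C_D(0)·V_D/(V_D+V_A)` and
  `Pe = −ln(1 − C_A(t)/C_eq)·V_D·V_A/((V_D+V_A)·A·t)`, t in seconds. The
  donor-side concentration field is carried for provenance but unused by this
  form. Classification: −log Pe < 6 permeable, 6–6.5 intermediate, > 6.5
  impermeable. Plate geometry (150/300 µL, 0.3 cm², 24 h) is a default, not a
  constant.
* **Activity kinetics**: ΔAbs = blank-corrected absorbance change at the read
  time (linear interpolation between samples), plus an initial rate from a
  least-squares slope over the first 30 min (window configurable).
* **Docking energetics**: `Kd = exp(ΔG/RT)` with R = 1.9872×10⁻³
  kcal mol⁻¹ K⁻¹ and T = 298 K by default.

## Synthetic data: what it emulates

`SimulationConfig` encodes the study conditions: 3 replicates; t-LiP doses 1
and 10 µM; LiP suppression 0.2 (a five-fold area drop for
subtilisin-sensitive peptides); protection FC 2.0; 10% CV multiplicative
log-normal noise on areas; 35% of non-planted peptides are LiP decoys
(suppressed but not protected — roughly the fraction of a folded protein that
is protease-accessible); DARTS doses 1/10/100 µM with target protection
40/60/80% over a uniform 0–10% background and a vehicle digestion-survival
fraction of 0.25; growth curves with GI50 17 µM, Hill 1, and 5-percentage-
point Gaussian noise.

The synthetic protein is a uniform-random sequence with K+R frequency ≈ 11%
(the tryptic-site density of real proteomes). Proteins ≥ 823 residues carry
the phosphorylase-fold annotation track verbatim (cap loop 41–48, helix 2
49–77, β4/β5 loop 180–198, tower helices 259–278, gate loop 279–289, N-domain
22–484, C-domain 485–822, Tyr75, Tyr196, with the two tyrosines planted in
the sequence); shorter proteins get the track scaled linearly.

Planted protection intervals snap to the nearest monitored tryptic peptide
(maximal overlap, then residue distance) because only fully tryptic peptides
within the MRM length bounds are quantifiable; the truth file records the
realized (snapped) intervals, which are authoritative for recovery checks.
DARTS dose scores interpolate between the controls so the planted protection
is realised exactly, then pick up noise; the controls stay noise-free so that
the zero-noise limit reproduces the planted percentages without error.
In recovery analyses the replicate-intersection floor is set to 20%, between
the background ceiling (10%) and the weakest planted dose effect (40%).

What the generators do **not** emulate: retention-time drift and peak-shape
anomalies, transition interference, search-engine score saturation,
correlated (batch) noise across peptides or replicates, missing-at-random
dropout, and real protein sequence composition. Passing recovery tests
therefore demonstrates the correctness and statistical behaviour of the
pipeline under its stated noise model, not robustness to every pathology of
real LC-MS data.

## Numerical choices and edge cases

* Welch tests on identical (zero-variance) groups return a NaN p-value from
  scipy; these are reported as p = 1 (no evidence), so noiseless data never
  produce spurious significance.
* Protection and fold-change ratios are exact in floating point at zero noise
  (the generators multiply by the planted factors, and means of identical
  replicates preserve power-of-two scalings), so the zero-noise tests assert
  exact equality.
* Gaussian chromatograms are rendered over ±6σ at 0.005-min sampling;
  trapezoidal integration then recovers the analytic area far inside the 1%
  tolerance.
* `fit_gi50` bounds the Hill slope to [0.05, 20] and the midpoint to positive
  values; bootstrap refits that fail to converge are dropped from the CI.
* Interval merging treats bookended intervals (end + 1 = next start) as one
  region, matching contiguous tryptic peptides.

## Problem sizes

The recovery analyses (also run by `scripts/acceptance.py`) use: 300 random
sequences × 3 missed-cleavage settings for the digestion-oracle check
(500 in the test suite); 500–1000 random peptides for the b/y identity;
100 noisy t-LiP runs on a 900-residue protein (~56 monitored peptides);
200 DARTS simulations of 300 proteins × 3 replicates × 3 doses; 200 GI50
fits of 8-dose curves; 25 rendered chromatographic peaks. These sizes give
stable rates (binomial SE ≲ 3 percentage points on the recovery percentages)
while keeping a full run under a minute on one CPU.
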