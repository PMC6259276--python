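# Methods

## The model

The analysis relates the TRPA1 agonist potency (pEC₅₀, log units) of 26
tricyclic analogues to molecular interaction fields sampled on a common 3D
lattice. Two descriptor families are used:

**CoMFA** energies between each molecule and an sp³ carbon probe of charge
+1 e at every lattice point *q*:

* steric: Lennard-Jones 6-12, E(q) = Σᵢ εᵢ[(R*ᵢ/rᵢ)¹² − 2(R*ᵢ/rᵢ)⁶], with
  pair parameters combined as R*ᵢ = r*ᵢ + r*_probe and εᵢ = √(εᵢ ε_probe)
  from an element-typed published table (`data/vdw_params.csv`);
* electrostatic: Coulomb, E(q) = Σᵢ 332.0636 qᵢ q_probe/(D(rᵢ)rᵢ) with the
  classic distance-dependent dielectric D(r) = r (a constant-dielectric
  alternative is available on the field functions).

Both are truncated at ±30 kcal/mol. At lattice points where a compound's
steric energy is truncated (probe inside the molecule) its electrostatic
value is replaced by the column mean of the untruncated compounds — the
conventional treatment of meaningless inside-atom electrostatics
(`electrostatic_mean_fill=False` switches it off). When every compound is
truncated at a point the value is 0; such columns are constant and are
removed by the column filter anyway.

**CoMSIA** Gaussian similarity indices, A(q) = −Σᵢ w_probe wᵢ exp(−α rᵢ²)
with attenuation factor α = 0.3 Å⁻², for five channels with atomic weights:
steric r_vdw³; electrostatic Gasteiger partial charge; hydrophobic Crippen
atomic logP increments; donor/acceptor 0/1 flags from simple typing rules
(O–H/N–H heavy atoms donate; O, and N with an available lone pair, accept —
amide N is donor-only). The kernel has no singularity, so no truncation.

The lattice is world-axis aligned in the template frame, 1.0 Å spacing,
and extends to the smallest box keeping every atom ≥ 4.0 Å inside the
faces (dimensions rounded up). Points are enumerated x-fastest.

## Structures and alignment

Structures are built from descriptors (scaffold bridge atom + one
substituent token) on an atom-indexed parent scaffold; the position-label →
atom-index map is documented in `src/trpa1_qsar/data/README.md`. One 3D
conformer per compound is generated with ETKDG (fixed seed), minimized with
MMFF94 (UFF fallback; 2000 iterations / 1e-6 kcal·mol⁻¹ tolerance), and
Gasteiger-charged.

The original study minimized with the Tripos force field under
Gasteiger–Hückel charges inside SYBYL. **Both components are proprietary**;
MMFF94 + plain Gasteiger is this package's substitution. Consequences:
conformer geometries, charges and hence field matrices differ numerically
from the published ones, which is why field-layer statistics are checked by
properties rather than against printed values (below).

Every compound is rigidly superimposed on compound 10 (the most active
analogue) by a Kabsch least-squares fit over the 14 heavy atoms of the
shared (Z)-N-benzylidenebenzenamine fragment. The fragment matches each
molecule more than once (the two phenyls are topologically
interchangeable); all match pairings are scored and the lowest-RMSD one is
kept, ties broken by lowest atom-index order. Hydrogens are excluded from
the fit (the published account does not state whether they were included;
heavy-atom fitting is the conservative reading). Across the series the core
RMSD averages ≈ 0.4 Å — the azomethine core is rigid, but the
seven-membered-ring pucker varies slightly with the bridge atom.

## PLS engine

Columns whose sample standard deviation across training compounds falls
below 2.0 are dropped (SYBYL-style "minimum sigma" filtering; the published
setting is 2.0 kcal/mol). The threshold is expressed in each channel's own
units. On this dataset the CoMFA energy channels keep ~1500 columns while
of the dimensionless CoMSIA channels only the steric one (atomic weights
r_vdw³ ≈ 5) reaches that variance — the remaining similarity channels vary
on a scale ≪ 2 and are filtered out entirely, so the refit CoMSIA model is
effectively steric-only and its printed field-contribution split cannot be
reproduced at this threshold. This is a faithful application of the stated
default to dimensionless fields, and the filter threshold is configurable
(`RunConfig.filter_threshold`) for users who want the similarity channels
retained.

Retained blocks are centered and block-scaled (CoMFA-standard: one pooled
divisor per channel so every field block carries equal overall variance;
"autoscale" and "none" are available). The PLS1 fit is NIPALS with
deflation; coefficients are mapped back to original column units, so the
model predicts from raw field matrices. With as many components as the rank
of X the fit coincides with ordinary least squares (tested to 1e-8).

Leave-one-out cross-validation refits the model without each training
compound and predicts it, for 1..10 components; q² (r²cv) is
1 − PRESS/SS_tot with SS_tot about the **full** training mean (whether the
original analysis used the fold-reduced mean is not stated; the full mean
is the common convention and is used consistently). The optimum component
count (ONC) is the smallest count attaining the maximal q². Internal
diagnostics at the ONC: r², SEE = √(SS_res/(n−c−1)),
F = (r²/c)/((1−r²)/(n−c−1)), and per-channel contributions
Σⱼ|bⱼ|σⱼ (scaled space), normalized across channels.

## External validation

For the 5 held-out compounds: r²_pred = (SD − PRESS)/SD, where SD is taken
about the training-mean activity; through-origin slopes k = Σyŷ/Σŷ² and
k′ = Σyŷ/Σy² (both reported — the published slope agrees with the first
convention); r₀² = 1 − Σ(ŷ − k′y)²/Σ(ŷ − ȳ̂)² and its primed counterpart;
Roy's rm² = r²(1 − √|r² − r₀²|) using the **training** r² and the test-set
r₀², which is the arithmetic that reproduces the published values exactly
(the absolute value covers the CoMSIA case, where r₀² > r²); and the
criteria battery q² > 0.5, r² > 0.6, (r²−r₀²)/r² < 0.1, 0.85 ≤ k ≤ 1.15,
rm² > 0.5.

Two caveats found while reconciling the printed constants, flagged rather
than resolved: the published r₀² equals the published k to three decimals
for both models and is **not** reproducible from the per-compound table by
the standard through-origin formula (recomputation gives 0.977/0.983); and
the recomputed CoMFA r²_pred is 0.972 vs the printed 0.967 — consistent
with 3-decimal rounding plus an unstated mean convention. The rm²/ratio
reference values are therefore computed from the printed summary constants,
everything else from the per-compound table.

## Contour maps

STDEV*COEFF fields put σⱼ·coefⱼ at each retained column's grid point (0 at
filtered columns). "Contour by contribution" levels: the favored level is
the smallest positive value whose upper tail holds at most
(100 − favored_pct)% of the total positive |σ·coef| mass (favored_pct = 80
→ the top 20% of mass); the disfavored level mirrors this on the negative
side with disfavored_pct. The published maps state only "80%/20%
contribution"; this cumulative-mass reading is the conventional one, and an
absolute-level alternative is trivially available by passing explicit
levels to the DX writer. Fields export as text OpenDX grids (x-fastest
internal order, z-fastest on disk, round-trip tested to 1e-6).

## Synthetic data

`gen_linear_dataset` emulates the statistical shape of a field/activity
dataset: columns are moving-average-smoothed standard normals (local
correlation, like neighbouring lattice points), activity is a sparse linear
combination (10 active of 500 columns) plus Gaussian noise of 0.3 log units
— the residual scale a good model of this series leaves. The correlation
length (100 columns) was fixed once by Monte-Carlo calibration: it is the
column smoothness at which a 21-sample LOO PLS achieves q² > 0.5 for ≥ 90%
of seeds, as a well-posed dataset of this shape should; at much shorter
correlation lengths the effective dimensionality overwhelms 21 samples and
no method cross-validates. Coefficient-recovery experiments run with fewer
columns (30) than samples (40): with p ≫ n the sparse true coefficient
direction is not identifiable from the design, so recovery is only a
meaningful property in the p < n regime (median cosine ≈ 0.89 at noise
0.1). What the generator does *not* emulate: realistic energy magnitudes,
truncation plateaus, inter-channel structure, or activity cliffs — passing
synthetic tests therefore validates the estimator chain, not the chemistry.

`gen_perturbed_series` jitters a conformer's coordinates with isotropic
Gaussian noise to exercise the alignment stage (aligned RMSD must never
exceed unaligned, and must grow monotonically with the jitter scale).

## Numerical choices and degenerate inputs

* NIPALS stops early if the weight or score norm underflows (1e-14);
  requested components are then truncated.
* Zero-variance y, empty conformer sets, zero grid spacing, all-columns
  -filtered matrices, and non-positive EC₅₀ raise informative errors.
* Probe-on-atom singularities clamp to the truncation bound, never crash.
* Sample standard deviation (ddof=1) is used for column filtering and
  contour σ; the pooled block scale uses ddof=0.
* Determinism: conformer embedding is seeded per compound (base seed in
  `RunConfig.seed`); repeated runs with the same configuration produce
  byte-identical reports.

## Problem sizes

The full pipeline (26 compounds, ~11600-point lattice, 7 channels, two
LOO-selected PLS models) completes in a few seconds on one CPU; the
synthetic calibration and recovery suites use 50 seeds each and run in
~2 s. All packaged data are small CSV/JSON text files.

## Known limitations

* Field-layer statistics are force-field- and charge-scheme-dependent; with
  the open substitutions the training fits are strong (r² ≈ 0.97–1.00) but
  LOO q² is well below the published SYBYL values (0.2 vs 0.63 for CoMFA) —
  single-conformer 3D-QSAR q² is notoriously sensitive to alignment and
  charge details.
* The 2.0 minimum-sigma filter applied to dimensionless CoMSIA indices
  reduces that model to its steric channel (discussed above).
* One conformer per compound; no conformational search, tautomers, or
  stereochemistry beyond the ring-constrained azomethine geometry.
* Position labels for the two scaffolds are fixed from the published
  structure drawing once; transcription inconsistencies in the source
  tables are noted in the data README and resolved in favour of the
  structure table.
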