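# Packaged data

All study data are transcribed from the published compound and activity
tables of the dibenzazepine / dibenzoxazepine TRPA1 agonist series; no
machine-readable deposition exists, so the CSVs here are the primary inputs.

## `compounds.csv`

One row per analogue: substituent position label, substituent group token,
bridge atom at the 11-position (O, CH2 or S), actual pEC50, and the
train/test assignment (5 test compounds: 7, 13, 15, 16, 25).

Ring-position numbering used by `position_map` in
`trpa1_qsar.compounds.SCAFFOLDS` (fixed once from the published structure
drawing):

* central seven-membered ring: N5=C6 azomethine, bridge atom at 11;
* benzo ring fused between N5 and the bridge: positions 1-4
  (1 is peri to the bridge, 4 is ortho to the C4a-N5 attachment);
* benzo ring fused between C6 and the bridge: positions 7-10
  (7 is ortho to the C6a-C6 attachment, 10 is peri to the bridge).

Known transcription issues in the printed source are noted in the CSV
header comments (compound 8 "COOMe2" -> COOMe; compounds 13 and 24 are
labelled inconsistently between the structure table and the SAR text —
the structure-table assignment is used).

## `predictions_table2.csv`

Actual pEC50, CoMFA/CoMSIA predicted pEC50 and printed residuals
(actual − predicted) for all 26 compounds. This table drives the
exactly-verifiable statistics layer (`pipeline.stats_only_report`).

## `reference_stats.json`

The printed PLS summary and external-validation constants for both models
(r²cv, r², ONC, SEE, F, field contributions, r²pred, k, r0², rm², ratio).
Used only as reference values to compare recomputed statistics against,
and as the printed-constant inputs of the rm² arithmetic.

## `vdw_params.csv`

Element-typed Lennard-Jones parameters (Tripos-5.2-style published values)
for the CoMFA steric probe energies.
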