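# trpa1-qsar

3D-QSAR (CoMFA/CoMSIA) analysis of 26 dibenz[*b*,*e*]azepine and
dibenz[*b*,*f*][1,4]oxazepine agonists of the human TRPA1 cation channel.

The series shares a tricyclic core — two benzo rings fused to a
seven-membered ring carrying an azomethine (C=N) and a variable bridge atom
(O, CH₂ or S) — decorated with one ring substituent. Activities span
pEC₅₀ = 6.030–10.301 (pEC₅₀ = log₁₀(1/EC₅₀), EC₅₀ in mol/L). The package
rebuilds the full modelling chain from the printed data tables:

1. **Structures** — each analogue is constructed from its scaffold +
   substituent descriptor, embedded in 3D, MMFF94-minimized and
   Gasteiger-charged, then rigidly superimposed (Kabsch) on the most active
   compound through the shared (Z)-N-benzylidenebenzenamine core.
2. **Fields** — on a 1 Å lattice with a 4 Å margin, CoMFA probe energies
   (Lennard-Jones 6-12 steric and Coulomb electrostatic with D(r)=r, both
   truncated at ±30 kcal/mol) and CoMSIA Gaussian similarity indices
   (steric, electrostatic, hydrophobic, H-bond donor/acceptor;
   A(q) = −Σᵢ w_probe wᵢ exp(−0.3 r²)) for an sp³ C⁺¹ probe.
3. **PLS** — minimum-sigma 2.0 column filtering, CoMFA-standard block
   scaling, NIPALS PLS1, leave-one-out cross-validation
   (q² = 1 − PRESS/SS_tot) with the component count chosen to maximize q²,
   and internal diagnostics r², SEE = √(SS_res/(n−c−1)),
   F = (r²/c)/((1−r²)/(n−c−1)), per-field contributions Σ|bⱼ|σⱼ.
4. **External validation** — on the 5-compound test set:
   r²_pred = (SD−PRESS)/SD, through-origin slopes k and k′, r₀², Roy's
   rm² = r²(1−√|r²−r₀²|), and the acceptance battery
   (q² > 0.5, r² > 0.6, (r²−r₀²)/r² < 0.1, 0.85 ≤ k ≤ 1.15, rm² > 0.5).
5. **Contours** — STDEV*COEFF fields per channel with 80%/20%
   contribution levels, exported as OpenDX grids.

The statistics layer (3–4) is *exactly* verifiable from the published
per-compound table and is the package's reference result. The
structure/field layer necessarily substitutes open components (MMFF94,
plain Gasteiger) for the proprietary Tripos force field and
Gasteiger–Hückel charges, so its field matrices — and hence q²/r² — differ
from the published SYBYL values; see `docs/methods.md`.

## Worked example

```python
>>> from trpa1_qsar.pipeline import stats_only_report
>>> rep = stats_only_report()
>>> c = rep["comfa"]["recomputed_from_table2"]
>>> round(c["r2"], 3), round(c["see"], 3), round(c["f_value"], 1)
(0.986, 0.154, 160.6)
>>> round(c["r2_pred"], 3)
0.972
>>> round(rep["comfa"]["from_printed_constants"]["rm_sq"], 3)
0.942
```

The training fit of the CoMFA model explains 98.6% of the activity variance
with a standard error of 0.154 log units (F = 160.6 at 6 components); the
model predicts the held-out test compounds with r²_pred ≈ 0.97, and Roy's
rm² = 0.942 clears the >0.5 external-validation threshold comfortably.

The full structure-based chain, and each stage separately, runs from the
numbered drivers:

```sh
python analysis/01_encode_dataset.py      # structures from descriptors
python analysis/02_prepare_conformers.py  # 3D, charges, alignment
python analysis/03_field_matrices.py      # CoMFA/CoMSIA lattice fields
python analysis/04_fit_models.py          # filtered PLS + LOO
python analysis/05_external_validation.py # test-set statistics
python analysis/06_contour_maps.py        # STDEV*COEFF OpenDX export
```

Tables land in `results/`, bulky artifacts (SDF, field archives, DX grids)
in `scratch/`.

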