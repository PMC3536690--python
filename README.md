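# comfa3d

A CoMFA-style 3D-QSAR pipeline for a packaged 46-compound congeneric
series of cytotoxic 3,5-diaryl-4,5-dihydropyrazole analogs (30 training,
16 external test compounds), built so that every stage is testable offline:

* **compound_library** — activity table loading/validation, pIC50
  transform, molecular-formula arithmetic (percent composition on average
  atomic weights, protonated-ion m/z on monoisotopic masses) used to
  cross-check the packaged SMILES against published characterization data;
* **conformer_alignment** — seeded single-conformer 3D embedding (ETKDG +
  MMFF relaxation), Gasteiger charges, rigid Kabsch superposition of a
  shared dihydropyrazole core onto the reference compound D5, and a small
  pharmacophore feature perception/mapping rule set (2 HBA + 3 hydrophobes);
* **field_engine** — 2.0 Å lattice extended 4.0 Å beyond the series,
  truncated Lennard-Jones steric and distance-dependent-dielectric Coulomb
  electrostatic energies of an sp³-carbon probe (+1.0 e, 1.52 Å, 30 kcal/mol
  cutoff), minimum-sigma column filtering and CoMFA-standard block scaling;
* **qsar_pls** — deterministic NIPALS PLS, leave-one-out cross-validation
  (PRESS, q², SDEP; filtering/scaling re-estimated inside every fold),
  conventional statistics (r², SEE, F), field contribution fractions;
* **prediction_contours** — external-set prediction and validation
  statistics, favored/disfavored contour thresholds of the coefficient·sd
  map (nearest-rank percentiles, default levels 80/20), Gaussian cube /
  OpenDX grid export, JSON+CSV report bundle;
* **synthetic_data** — planted-signal field matrices, toy congeneric 3D
  series with exactly known activity mechanism, and y-scrambling nulls.

## CLI

```bash
qsar compounds validate                 # dataset + characterization check
qsar align --template D5 --seed 7       # aligned SDF + core-RMSD report
qsar fields --spacing 2.0 --margin 4.0  # descriptor matrix CSV
qsar run --components 6 --seed 7 --out qsar_report   # full pipeline bundle
qsar simulate fields --seed 3 --out sim # synthetic planted-signal dataset
qsar simulate series --seed 3 --out ser # synthetic congeneric 3D series
```

`qsar run` writes `report.json`, `training_predictions.csv`,
`test_predictions.csv` and `contours_{steric,electrostatic}.cube`.
Residuals are always observed − predicted.

## Reproduction notes

The headline model statistics of the original study depend on undisclosed
commercial-software internals (conformer selection, manual alignment
adjustments, scaling defaults) and are not promised to reproduce exactly.
The packaged deterministic run (seed 7, 6 components) achieves
r² ≈ 0.91 (published 0.895), steric/electrostatic contributions
≈ 0.41/0.59 (published 0.454/0.546), with df (6, 23) as published; q² and
external r² do not reproduce and are recorded alongside the published
values in the report bundle.
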