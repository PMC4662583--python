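# gridshield

Additive, grid-based prediction of protein backbone (and Cβ) chemical
shieldings from structure, with linear calibration against experimental
chemical shifts.

A per-atom shielding is assembled as a sum of terms

```
sigma = BB + BB_prev + BB_next + HB1 + HB2 + HaB1 + HaB2 + RC + W
```

* **BB** — tripeptide-baseline surface looked up at the residue's
  (φ, ψ, χ…) torsions,
* **BB_prev / BB_next** — neighbouring side-chain corrections, referenced
  to an alanine constant σ^A at (φ, ψ) = (−120°, 140°),
* **HB1 / HB2** — primary (donor-centered) and secondary
  (acceptor-centered) amide hydrogen-bond corrections over (r, θ, ρ),
* **HaB1 / HaB2** — the analogous Hα hydrogen-bond corrections,
* **RC** — point-dipole ring current `i·B·(1 − 3cos²θ)/r³` with an 8 Å
  cutoff,
* **W** — a 2.07 ppm explicit-water correction for amide protons without
  an intra-protein partner.

Which terms contribute to which atom type (CA, CB, C, HA, HN, N) is
data — a `TermMask` whose default matches the published selection — so
ablation experiments are one override away.  The quantum-derived lookup
tables are treated as replaceable data: a *grid bundle* is a directory of
`manifest.json` plus raw little-endian float64 arrays, and the `synth`
module generates fully self-consistent synthetic bundles so the entire
pipeline is testable with no external downloads.

Predicted shieldings are converted to shifts by per-atom-type ordinary
least squares in the `delta = b − a·sigma` convention; reports include
RMSD after regression, |Pearson r|, optional random-coil correction and
generalized-ESD outlier flags.

## Command line

```sh
# generate a seeded synthetic bundle + toy structure + noisy shifts
gridshield make-fixtures --out-dir fx --seed 7

# per-atom term breakdown (TSV)
gridshield predict --structure fx/toy.pdb --bundle fx/bundle \
    --output report.tsv

# ablation: restrict CB to the backbone term only
gridshield predict --structure fx/toy.pdb --bundle fx/bundle \
    --output report.tsv --mask CB=BB

# calibrate against a shift table (per-atom-type a, b, RMSD, |r|, outliers)
gridshield calibrate --structure fx/toy.pdb --bundle fx/bundle \
    --shifts fx/shifts.tsv --output calibration.tsv

gridshield inspect-grid --bundle fx/bundle
```

Multi-MODEL PDB files are ensemble-averaged (mean shielding per nucleus
across models, then a single regression), matching the
average-then-regress protocol.  Missing amide hydrogens can be built
(`--hydrogens build`, the default) in the C(i−1)–N–CA plane at 1.01 Å.

## Layout

```
src/gridshield/
  model_io.py     PDB/ensemble parsing, H building, shift tables, reports
  geometry.py     torsions, H-bond (r, θ, ρ) frames, ring systems/currents
  grids.py        periodic cubic / nearest-neighbour interpolation, bundles
  terms.py        individual shielding terms
  predictor.py    term-mask assembly, ensemble averaging
  calibration.py  OLS calibration, RMSD/|r|, GESD outliers, random coil
  synth.py        synthetic bundles, toy structures, noisy observations
  cli.py          click entry points
```
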