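# halopi

Pipeline for scoring halogen···π (σ-hole) interactions between halobenzenes
and benzene:

- **molgeom** — idealized benzene / halobenzene builders, rigid transforms,
  ring plane math, XYZ I/O.
- **geomgen** — systematic pose-grid enumeration (508,032 poses per
  halobenzene at the default settings) and unique random pose sampling.
- **features** — the 30-component geometric descriptor (27 distances + 3
  angles, halogen-distance-sorted ring blocks) and min-max scaling.
- **surrogate** — analytic stand-in for quantum-chemical adduct formation
  energies (directional attractive well, halogen ordering Cl < Br < I,
  repulsive wall, optional noise) plus ingestion of externally computed
  complex/monomer energy tables.
- **model** — stratified train/val/test splitting, a 64/32/16 leaky-ReLU
  feed-forward regressor (Adam, imbalance-weighted MSE with elastic-net
  penalties, LR halving to a 1e-4 floor, early stopping), evaluation
  (R², RMSE, MAE, clipped ΔΔE histogram) and JSON checkpoints.
- **applicability** — Mahalanobis-distance applicability domain with a
  95th-percentile outlier threshold.
- **pdbscan** — PDB mining for halogen···PHE contacts, σ-hole geometry
  filters, and matched-molecular-pair reconstruction of canonical
  halobenzene–benzene complexes.

## CLI

```bash
halopi generate-grid --halogen I --count-only --out grid        # 508032
halopi generate-random --halogen Br --n 1000 --seed 7 --out rnd
halopi simulate-energies --mode grid --step 1.25 --noise-sd 0 --out ds
halopi train --data ds.csv --seed 0 --out model.json
halopi predict --model model.json --data ds.csv --out pred.csv
halopi evaluate --data pred.csv --out report.json
halopi scan-pdb --in structures/ --model model.json --out scan
```

Every command writes a `.manifest.json` next to its output (config
snapshot, seeds, row counts) for provenance.

## Units & conventions

Distances in Å, angles in degrees, energies in kJ/mol (1 hartree =
2625.4996 kJ/mol for ingested QM tables). The acceptor benzene lies in the
xz-plane with its centroid at the origin and plane normal +y; donors sit at
y > 0. A tilt angle α = 0° means the C–X axis points straight at the ring
plane.
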