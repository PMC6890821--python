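# mdflex

Analysis toolkit for conformational ensembles of two-lobe kinases (and
similar proteins): superposition-based flexibility metrics, essential-
dynamics PCA, NMR-observable validation diagnostics, and a
sphere-intersection classifier that maps solvent-mapping probe clusters
onto named binding pockets.

## What it does

- **structure_io** — multi-model PDB read/write, DCD/XTC adapters (via
  the optional MDAnalysis dependency), deterministic atom selection,
  formal-charge census with counterion bookkeeping, residue-level
  sequence diffs.
- **traj_metrics** — Kabsch superposition, per-frame RMSD series,
  all-to-all RMSD convergence matrices (pairwise fitting), per-residue
  RMSF profiles, 1-D density estimates, flexible-region reports for the
  six canonical kinase loops.
- **pca_modes** — combined-ensemble Cα PCA: eigenmodes, projections
  (trajectories and external crystal structures), variance accounting,
  extreme structures per PC, linear morphing, cross-ensemble mode
  overlap.
- **geometry** — atom/ring-center distance series, dihedral measurement
  (IUPAC sign convention), circular means for dihedral-restraint
  derivation, charged-residue distance matrices with an RMS discrepancy
  metric.
- **nmr_compare** — typed chemical-shift/RDC tables, ensemble
  averaging, OLS regression reports with ranked outliers, per-snapshot
  Pearson-R densities.
- **pocket_mapper** — bounding spheres, the analytic sphere-sphere
  intersection volume (0.75 scaling on the pocket sphere), argmax pocket
  assignment with ATP-site merging, consensus strength S and
  druggability calls (S ≥ 16).
- **synthetic_data** — seeded generators with exact ground truth: a
  two-domain toy protein, planted hinge ("butterfly") + twist modes,
  flexible loops, probe clusters around pocket sites, observable tables
  with known slope/intercept/outliers.

Packaged data (`src/mdflex/data/`): experimental RDC table (39
residues), charged-residue list (85 residues), pocket registry (19
pockets), and the eight ligand dihedral restraints.

## CLI

```sh
mdflex synth --out demo --seed 3 --frames 50     # synthetic demo dataset
mdflex metrics --reference demo/reference.pdb --trajectory demo/trajectory.pdb --out out
mdflex pca     --reference demo/reference.pdb --trajectory demo/trajectory.pdb --out out
mdflex nmr     --sim demo/sim_rdc.tsv --exp demo/exp_rdc.tsv --out out
mdflex pockets --reference demo/reference.pdb --clusters demo/probes.pdb \
               --registry demo/registry.tsv --out out
mdflex run     --config config.yaml              # config-driven, manifest + CSVs
```

`mdflex run` consumes a YAML config (paths, selections, strides,
thresholds, seed) and writes CSV outputs plus a `manifest.json` with the
config hash; reruns with identical config are byte-identical.

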