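# pepbind

Desk-scale toolkit for protein–protein interface energetics and head-to-tail
cyclic peptide design, built around the TNFα–TNFR1 system. It covers the full
computational loop: trajectory-style ensemble analysis (RMSD/RMSF, interface
residues, hydrogen-bond occupancy, DCCM), single-trajectory MM-PBSA binding
free energies with per-residue decomposition, computational alanine scanning
and hot-spot classification, peptide truncation + GP/CC cyclization with the
`R1/α_GP/CCX` naming scheme and 3-D macrocycle building, virtual point
mutation with re-scoring, and assay-side utilities (viability percentages,
one-site KD fitting).

Everything runs on a laptop with no external downloads: a synthetic-data
module generates toy two-chain complexes with a designed contact gap,
Gaussian coordinate ensembles with controlled fluctuation/correlation
structure, hydrogen-bond occupancy by construction, and noisy saturation
binding curves — all bit-reproducible from explicit seeds.

## Highlights

- **MM-PBSA engine**: all-pairs Coulomb and 12-6 Lennard-Jones cross terms,
  Shrake–Rupley SASA with the `γ·SASA + β` nonpolar model
  (γ = 0.00542 kcal·mol⁻¹·Å⁻², β = 0.92 kcal·mol⁻¹), and a finite-difference
  linearized Poisson–Boltzmann solver (7-point stencil, face dielectrics,
  Debye–Hückel screening, conjugate-gradient solve, vacuum reference on the
  identical grid). The PB solver lands within 1.5 % of the Born closed form
  for a unit-charge 2 Å sphere at 0.25 Å spacing.
- **Single-trajectory protocol**: complex, receptor and ligand are scored on
  the same coordinates, so internal bonded terms cancel identically and
  `ΔG_bind = ΔE_ele + ΔE_vdw + ΔG_PB + ΔG_nonp` holds exactly on every output.
- **Self-contained parameters**: a small, versioned YAML table (charges to
  two decimals on heavy atoms, one LJ class per element, Bondi-like radii)
  keeps every residue at its integer formal charge; it is not a force field
  and is not meant to be one.
- **Design layer**: the eleven linear truncation sequences plus the two
  literature control peptides ship as packaged fixtures; both cyclization
  strategies applied to the eleven sequences give the expected 22 designs,
  with ring geometries closed to the amide (1.33 Å) or disulfide (2.05 Å)
  targets.

## Command line

```sh
pepbind simulate --n-res-a 6 --n-res-b 6 --gap 4.5 --frames 20 --seed 1 --out toy
pepbind analyze rmsd --ensemble toy_ensemble.pdb --out rmsd.csv
pepbind mmpbsa --complex toy_ensemble.pdb --receptor chain:A --ligand chain:B \
    --out mmpbsa.csv --per-residue per_residue.csv
pepbind alascan --complex toy_ensemble.pdb --receptor chain:A --ligand chain:B \
    --out alascan.csv
pepbind design --out designs.fasta --build α_CC8
pepbind mutate --pdb model.pdb --spec L16R --chain A --out mutant.pdb
pepbind fit-kd --curve curve.csv --out fit.json
pepbind run --config config.yaml      # full 6-stage pipeline + manifest
```

The pipeline config is a single YAML file (see `pepbind.pipeline.RunConfig`
for the fields); identical config + seed produce byte-identical numeric
outputs, and the manifest records a sha256 for every file.

## Layout

| module | contents |
| --- | --- |
| `pepbind.structures` | PDB read/write, chain selection, fragment splicing |
| `pepbind.forcefield` | reduced parameter table, per-atom assignment |
| `pepbind.synthetic` | toy complexes, ensembles, H-bond and binding-curve generators |
| `pepbind.ensemble` | superposition, RMSD/RMSF, interface, H-bonds, DCCM |
| `pepbind.energetics` | pairwise terms, SASA, PB solver, MM-PBSA aggregation |
| `pepbind.scanning` | alanine scan, hot spots, point mutation |
| `pepbind.peptides` | truncation, cyclization, naming, ring building |
| `pepbind.assay` | viability formula, one-site KD fit |
| `pepbind.pipeline` / `pepbind.cli` | 6-stage workflow and CLI |
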