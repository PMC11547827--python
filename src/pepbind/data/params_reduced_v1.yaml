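# Reduced per-atom parameter table, version 1.
#
# Charges (e, 2 decimals) are assigned to heavy atoms only; hydrogens carry
# 0.00 via the element fallback.  Backbone atoms sum to 0.00 in every residue
# and each side chain sums to the residue's formal charge, so fragments and
# spliced peptides stay integer-charged without a capping protocol.
# Lennard-Jones classes are one per element (rmin/2 in Angstrom, epsilon in
# kcal/mol).  Solvation radii are Bondi-like van der Waals radii (Angstrom).
version: 1

lj_by_element:
  H: {rmin_half: 0.60, epsilon: 0.0157}
  C: {rmin_half: 1.908, epsilon: 0.086}
  N: {rmin_half: 1.824, epsilon: 0.17}
  O: {rmin_half: 1.661, epsilon: 0.21}
  S: {rmin_half: 2.00, epsilon: 0.25}

solv_radius_by_element:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80

# Charge fallback for atoms not named in the residue tables, keyed by element.
# Only hydrogen and terminal oxygen are covered; anything else is an error.
fallback_charges:
  H: 0.00

formal_charges:
  ALA: 0
  ARG: 1
  ASN: 0
  ASP: -1
  CYS: 0
  GLN: 0
  GLU: -1
  GLY: 0
  HIS: 0
  ILE: 0
  LEU: 0
  LYS: 1
  MET: 0
  PHE: 0
  PRO: 0
  SER: 0
  THR: 0
  TRP: 0
  TYR: 0
  VAL: 0

# Shared by all residues; sums to 0.00.  OXT (terminal carboxylate oxygen)
# is carried at 0.00 so termini do not change the integer residue charge.
backbone_charges:
  N: -0.40
  CA: 0.10
  C: 0.60
  O: -0.30
  OXT: 0.00

sidechain_charges:
  ALA: {CB: 0.00}
  ARG: {CB: 0.00, CG: 0.00, CD: 0.10, NE: 0.10, CZ: 0.40, NH1: 0.20, NH2: 0.20}
  ASN: {CB: 0.00, CG: 0.55, OD1: -0.55, ND2: 0.00}
  ASP: {CB: 0.00, CG: 0.40, OD1: -0.70, OD2: -0.70}
  CYS: {CB: 0.20, SG: -0.20}
  GLN: {CB: 0.00, CG: 0.00, CD: 0.55, OE1: -0.55, NE2: 0.00}
  GLU: {CB: 0.00, CG: 0.00, CD: 0.40, OE1: -0.70, OE2: -0.70}
  GLY: {}
  HIS: {CB: 0.00, CG: 0.10, ND1: -0.30, CD2: 0.00, CE1: 0.20, NE2: 0.00}
  ILE: {CB: 0.00, CG1: 0.00, CG2: 0.00, CD1: 0.00}
  LEU: {CB: 0.00, CG: 0.00, CD1: 0.00, CD2: 0.00}
  LYS: {CB: 0.00, CG: 0.00, CD: 0.00, CE: 0.20, NZ: 0.80}
  MET: {CB: 0.00, CG: 0.05, SD: -0.10, CE: 0.05}
  PHE: {CB: 0.00, CG: 0.00, CD1: 0.00, CD2: 0.00, CE1: 0.00, CE2: 0.00, CZ: 0.00}
  PRO: {CB: 0.00, CG: 0.00, CD: 0.00}
  SER: {CB: 0.25, OG: -0.25}
  THR: {CB: 0.25, OG1: -0.25, CG2: 0.00}
  TRP: {CB: 0.00, CG: 0.00, CD1: 0.10, CD2: 0.00, NE1: -0.30, CE2: 0.20, CE3: 0.00, CZ2: 0.00, CZ3: 0.00, CH2: 0.00}
  TYR: {CB: 0.00, CG: 0.00, CD1: 0.00, CD2: 0.00, CE1: 0.00, CE2: 0.00, CZ: 0.30, OH: -0.30}
  VAL: {CB: 0.00, CG1: 0.00, CG2: 0.00}
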