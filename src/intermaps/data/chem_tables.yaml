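# Per-atom chemistry tables: van der Waals radii, donor/acceptor roles,
# charge groups, aromatic rings, amino-pi donor groups and metal elements.
# Distances in Angstrom. Users may point the CLI at an edited copy
# (--chem-tables) to change any entry.
#
# Radii are the Bondi set (H from the Rowland & Taylor revision); elements
# not listed fall back to `default`.

vdw_radii:
  H: 1.10
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  Cl: 1.75
  Br: 1.85
  I: 1.98
  Se: 1.90
  Na: 2.27
  K: 2.75
  Mg: 1.73
  Ca: 2.31
  Mn: 2.05
  Fe: 2.05
  Co: 2.00
  Ni: 1.97
  Cu: 1.96
  Zn: 2.01
  Cd: 2.18
  default: 1.80

# Strong donor heavy atoms (N/O/S carrying at least one hydrogen).
# `_protein_backbone` applies to every amino acid except proline.
donors:
  _protein_backbone: [N]
  ARG: [NE, NH1, NH2]
  ASN: [ND2]
  GLN: [NE2]
  HIS: [ND1, NE2]   # ambiguous protonation: both treated as potential donors
  LYS: [NZ]
  SER: [OG]
  THR: [OG1]
  TRP: [NE1]
  TYR: [OH]
  CYS: [SG]
  A:  [N6, "O2'"]
  G:  [N1, N2, "O2'"]
  C:  [N4, "O2'"]
  U:  [N3, "O2'"]
  DA: [N6]
  DG: [N1, N2]
  DC: [N4]
  DT: [N3]

acceptors:
  _protein_backbone: [O, OXT]
  _nucleic_backbone: [OP1, OP2, O1P, O2P, "O3'", "O5'", "O4'", "O2'"]
  ASN: [OD1]
  ASP: [OD1, OD2]
  GLN: [OE1]
  GLU: [OE1, OE2]
  HIS: [ND1, NE2]
  MET: [SD]
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  CYS: [SG]
  A:  [N1, N3, N7]
  G:  [O6, N3, N7]
  C:  [O2, N3]
  U:  [O2, O4]
  DA: [N1, N3, N7]
  DG: [O6, N3, N7]
  DC: [O2, N3]
  DT: [O2, O4]

# Formal charge groups; each entry is a list of groups, each group a list of
# member atoms. Histidine's imidazole is included as cationic by default
# (positively ionisable); disable with the geometry-config switch
# `his_cationic`. N-terminal amines and C-terminal carboxylates are detected
# geometrically at annotation time.
cationic_groups:
  LYS: [[NZ]]
  ARG: [[NE, NH1, NH2]]
  HIS: [[ND1, NE2]]
anionic_groups:
  ASP: [[OD1, OD2]]
  GLU: [[OE1, OE2]]
  _nucleic_phosphate: [[OP1, OP2], [O1P, O2P]]

# Aromatic ring systems; 5- and 6-rings of fused systems are listed
# separately and detected per individual ring.
rings:
  PHE: [[CG, CD1, CE1, CZ, CE2, CD2]]
  TYR: [[CG, CD1, CE1, CZ, CE2, CD2]]
  TRP: [[CG, CD1, NE1, CE2, CD2], [CE2, CD2, CE3, CZ3, CH2, CZ2]]
  HIS: [[CG, ND1, CE1, NE2, CD2]]
  A:  [[N9, C8, N7, C5, C4], [C4, C5, C6, N1, C2, N3]]
  G:  [[N9, C8, N7, C5, C4], [C4, C5, C6, N1, C2, N3]]
  DA: [[N9, C8, N7, C5, C4], [C4, C5, C6, N1, C2, N3]]
  DG: [[N9, C8, N7, C5, C4], [C4, C5, C6, N1, C2, N3]]
  C:  [[N1, C2, N3, C4, C5, C6]]
  U:  [[N1, C2, N3, C4, C5, C6]]
  DC: [[N1, C2, N3, C4, C5, C6]]
  DT: [[N1, C2, N3, C4, C5, C6]]
  CLB: [[C1, C2, C3, C4, C5, C6]]   # chlorobenzene-like het used in fixtures

# Amide / guanidinium / exocyclic-amine nitrogens able to stack over a ring
# (amino-pi donors).
amino_pi_groups:
  ASN: [ND2]
  GLN: [NE2]
  ARG: [NE, NH1, NH2]
  A:  [N6]
  G:  [N2]
  C:  [N4]
  DA: [N6]
  DG: [N2]
  DC: [N4]

# Standard-residue carbons that carry no hydrogen (everything else with
# element C is assumed to bear at least one H and can act as a weak C-H
# donor in heavy-atom mode).
carbons_without_h:
  _protein_backbone: [C]
  ASP: [CG]
  GLU: [CD]
  ASN: [CG]
  GLN: [CD]
  ARG: [CZ]
  PHE: [CG]
  TYR: [CG, CZ]
  TRP: [CG, CD2, CE2]
  HIS: [CG]
  A:  [C4, C5, C6]
  G:  [C2, C4, C5, C6]
  C:  [C2, C4]
  U:  [C2, C4]
  DA: [C4, C5, C6]
  DG: [C2, C4, C5, C6]
  DC: [C2, C4]
  DT: [C2, C4, C5]

metal_elements: [Na, K, Mg, Ca, Mn, Fe, Co, Ni, Cu, Zn, Cd]
halogen_elements: [F, Cl, Br, I]
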