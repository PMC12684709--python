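# intermaps

Atomic-level interface analysis for biomolecular complexes.

Given the 3D structure (PDB or mmCIF) of a complex between protein, DNA
and/or RNA chains and a two-partner selection, `intermaps` detects every
inter-partner atomic interaction, classifies it into **16 classes** —
H-bonds, salt bridges, weak (C–H···O/N) H-bonds, water-mediated and
metal-mediated contacts, disulfide bonds, halogen bonds, the π family
(π–π, lone pair–π, anion–π, cation–π, amino–π, O/N/S–H···π, C–H···π) and
polar/apolar van der Waals contacts — and derives the interface's tabular
and graphical summaries: the Table of Atomic Interactions, residue-level
and by-type summary tables, pie-chart fractions, a per-residue-pair
interaction heatmap, per-class contact-map layers (the third dimension of a
3D contact map), and per-residue buried surface areas.

It is aimed at structural biologists and modellers who want a complete,
scriptable census of the physico-chemical contacts that stabilize an
interface — from hotspot salt bridges down to the hydration network —
without a web server in the loop.

## The model

Two residues are *in contact* when their minimum heavy-atom distance is
within a cutoff (default 5 Å). Each inter-partner atom pair inside the
contact shell is tested against geometric criteria, e.g. for an H-bond with
donor D, hydrogen H and acceptor A:

    d(D···A) ≤ 3.5 Å,  d(H···A) ≤ 2.7 Å,  ∠(D–H···A) ≥ 120°

and for a stacked π–π contact between rings with centroids c₁, c₂ and
normals n̂₁, n̂₂:

    |c₁ − c₂| ≤ 5.5 Å,  ∠(n̂₁, n̂₂) ≤ 30°,  lateral offset ≤ 2.5 Å.

Every threshold is a named, range-checked parameter (`intermaps config`
prints the full table). Missing polar hydrogens are placed at ideal
geometry (N–H 1.01 Å, O–H 0.96 Å, rotatable hydroxyls aimed at the nearest
acceptor); a heavy-atom mode replaces H-dependent criteria with donor-angle
surrogates. A strict precedence (disulfide > salt bridge > H-bond > halogen
bond > weak H-bond > π > vdW) guarantees one record per atom pair;
water/metal bridges are recorded in addition. Atom pairs closer than the
sum of their van der Waals radii are *clashes*: a contact that still meets
a class's geometry keeps its class, flagged with an asterisk (`hbond*`).
In-cutoff residue pairs matching no class are reported once as *proximal*.

Solvent-accessible surface area uses the Shrake–Rupley construction on a
deterministic golden-spiral lattice (default 960 points, probe 1.4 Å); the
buried surface area of a residue is BSA = ASA(isolated partner) −
ASA(complex), and the interface area is the mean of the two partners'
buried totals.

## Worked example

The package ships a synthetic-fixture generator that plants ideal-geometry
instances of any interaction class (used throughout the test suite). Plant
four motifs and analyze them:

```sh
python - <<'EOF'
from intermaps.fixtures import make_mini_complex
pdb, _ = make_mini_complex(4, seed=7,
    classes=["salt_bridge", "pi_pi", "water_mediated", "ch_pi"])
open("demo.pdb", "w").write(pdb)
EOF
intermaps analyze --in demo.pdb --p1 A --p2 B --out demo_run
```

The log reports `4 residue pairs, 4 atomic interactions (4 directional)`,
and `demo_run/interactions.tsv` lists exactly the planted contacts:

```
chain1 resnum1 resname1 atom1                       chain2 resnum2 resname2 atom2                       class          distance_A mediator
A      1       ASP      OD1                         B      1       LYS      NZ                          salt_bridge    3.40
A      2       PHE      ring(CG-CD1-CE1-CZ-CE2-CD2) B      2       PHE      ring(CG-CD1-CE1-CZ-CE2-CD2) pi_pi          3.80
A      3       SER      OG                          B      3       ASN      OD1                         water_mediated 2.80       W:1:HOH/O
A      4       ALA      CB                          B      4       PHE      ring(CG-CD1-CE1-CZ-CE2-CD2) ch_pi          4.20
```

`demo_run/summary.json` gives the by-class census (each planted class
counted once, `directional_total: 4`) and the buried areas
(`partner1: 116.13 Å², partner2: 109.58 Å², interface_area: 112.86 Å²`);
`heatmap.tsv` and `layers/<class>.tsv` hold the contact-map matrices. A
salt bridge at 3.40 Å between Asp OD1 and Lys NZ and a stacked π–π pair at
3.80 Å centroid separation are exactly what the generator planted — the
analysis recovers the ground truth.

Real structures work the same way, e.g. the barnase–barstar complex with
partner selections `--p1 A --p2 D`, or part-of-chain selections such as
`--p1 B:34-36 --p2 A:403-461` for a tRNA anticodon against a binding
domain. Thresholds are overridable within their allowed ranges:
`--set hbond.da_max=3.3 --cutoff 4.5`.

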