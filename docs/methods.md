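# Methods

## Scope and model

`intermaps` analyzes one conformation of a biomolecular complex. The input
hierarchy is chains → residues → atoms; only the first model of a
multi-model (NMR) file is used, and alternate conformers are collapsed to
the highest-occupancy altloc (ties resolved toward altloc `A`). Author
residue numbering with insertion codes is kept throughout; selection ranges
are inclusive. Waters (HOH/WAT/DOD) and single-atom metal ions are never
part of a partner — they participate only as bridge mediators. Other het
groups (ligands, modified residues) belong to whichever partner's chain
they sit in.

An *interface* is the set of inter-partner residue pairs whose minimum
heavy-atom distance is within `residue_cutoff` (default 5 Å; an all-atom
switch exists). Interaction detection runs per atom pair (or atom/ring and
ring/ring pair) inside that shell, using KD-trees for neighbor queries so
cost stays near-linear in atom count.

## Interaction criteria

All detectors are pure geometric predicates over annotated atoms. Per-atom
chemistry (Bondi van der Waals radii with the 1.10 Å revised hydrogen
radius, donor/acceptor roles, charge groups, aromatic-ring membership,
halogen/metal/water flags) comes from an editable YAML table covering the
20 amino acids and the standard (deoxy)ribonucleotides; unknown residues
fall back to element rules (N/O polar, C/S apolar, element radius) so
annotation is total.

Defaults (all user-overridable within stated ranges; distances in Å,
angles in degrees):

| class | criteria (defaults) |
|---|---|
| hbond | D···A ≤ 3.5, H···A ≤ 2.7, ∠D–H···A ≥ 120 (heavy-atom mode: ∠C–D···A ≥ 90 surrogate) |
| salt_bridge | anionic-group O/N to cationic-group N ≤ 4.0, one record per group pair |
| weak_hbond | C···A ≤ 3.8 with explicit C–H criteria (H···A ≤ 2.8, ∠ ≥ 110) when the input carries the H |
| water_mediated | water O within 3.5 of an O/N atom on each partner; one record per (atom, atom, water) |
| metal_mediated | ion within 2.8 (Mg/Zn/Mn/Fe/Co/Ni/Cu/Cd) or 3.0 (Na/K/Ca) of O/N/S on each partner |
| disulfide | Cys SG–SG ≤ 2.5 |
| halogen_bond | X···A ≤ vdW sum + 0.2, ∠C–X···A ≥ 140, A ∈ {O, N, S} |
| pi_pi | centroids ≤ 5.5; stacked (planes ≤ 30°, offset ≤ 2.5) or T-shaped (60–90°) |
| cation_pi | cationic N to centroid ≤ 6.0, axial angle ≤ 45 |
| anion_pi | anionic O to centroid ≤ 5.0, axial ≤ 45 |
| lone_pair_pi | neutral acceptor O/N ≤ 3.7, axial ≤ 40, no attached H within 50° of the ring direction |
| amino_pi | amide/guanidinium/exocyclic-amine N ≤ 5.5, axial ≤ 50 |
| onsh_pi | O/N/S donor: H···centroid ≤ 3.5 (heavy mode: donor ≤ 4.0), axial ≤ 40 |
| ch_pi | C–H: H···centroid ≤ 3.5 (heavy mode: C ≤ 4.5), axial ≤ 55 |
| vdw | d ≤ vdW sum + 0.5; *polar* when either atom is N/O, else *apolar* |

Clash: any heavy-atom pair with d < vdW sum (tolerance 0). A clashing pair
that meets a class's geometry keeps the class with an asterisk flag;
otherwise a clash-flagged vdW record is emitted. Disulfides are exempt —
the S–S separation is a covalent bond, not a steric violation. Residue
pairs inside the cutoff with no classified atomic interaction carry exactly
one *proximal* record (closest heavy-atom pair named).

### Precedence and coverage

Detectors run as independent predicates; a resolution pass then accepts
candidates strongest-first (disulfide > salt bridge > hbond > halogen >
weak hbond > π family > vdW), so one direct atom pair yields at most one
non-mediated record. Within the π family the order is cation > anion >
lone pair > amino > O/N/S–H > C–H (charged before neutral, specific before
generic); ring–ring π–π never competes with atom probes. Each accepted
record *covers* its constituent atom pairs (both charge groups of a salt
bridge; probe × ring atoms for π contacts; ring × ring for π–π; the
S–S unit plus its bonded neighbors for disulfides) and covered pairs are
not re-reported as vdW. Two further conventions avoid double counting:
for fused ring systems (Trp, purines) a contact satisfying both rings is
reported once with the shorter centroid distance; and a probe covalently
bonded to an already-accepted probe on the same ring (e.g. the C–H
adjacent to an accepted O–H···π donor) is taken as part of the same
physical contact and dropped. Mediated (water/metal) records are
additional and unlimited; a bridge whose end residues are farther apart
than the residue cutoff still appears as its own residue-pair row, so
`min_distance ≤ cutoff` holds for all rows except mediated-only ones.

### Hydrogen handling

In the default `explicit` mode, polar hydrogens are placed at ideal
geometry for residues that arrive without any hydrogens: backbone amide H
anti to the preceding carbonyl, sp² N–H on ring/amide planes, staggered
sp³ ammonium H, and rotatable hydroxyls (Ser/Thr/Tyr/Cys, ribose O2′)
aimed at the nearest acceptor within 3.5 Å (staggered default otherwise).
Bond lengths: N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å. Existing hydrogens are
trusted and never moved; placement only appends. Nonpolar (C–H) hydrogens
are not placed: carbon donors are evaluated with heavy-atom criteria
unless the input supplied the hydrogens. Water hydrogens are never placed;
water bridges use oxygen-only distance criteria, since water H orientation
is unobservable in most crystal structures. Histidine is treated as
ambiguously protonated: both ND1 and NE2 act as potential donors *and*
acceptors, and the imidazole counts as a cationic group by default
(switch: `his_cationic`). Salt bridges are distance-only by default
(`salt_bridge_requires_hbond` switches on the stricter convention).

## Surface burial

Shrake–Rupley sampling on a golden-spiral (Fibonacci) lattice: area =
4π(r+p)² × accessible/n, a point being accessible when outside every
neighbor's solvent-expanded sphere. The lattice is deterministic, so
identical inputs give bitwise-identical areas. Defaults: probe 1.4 Å, 960
points (isolated-atom closed form exact; two-sphere analytic solution
reproduced to well under 1%; 960 vs 4000 points differ by ≈0.1–0.2% summed
over a structure). Hydrogens, waters and ions are excluded by default so
BSA = ASA(free partner) − ASA(complex) measures partner–partner burial
only; residues with BSA > 0.1 Å² count as interface residues. The
symmetric "interface area" is the mean of the two partners' buried totals.

## Reporting conventions

`directional_total` counts all classes except the two vdW classes and
proximal. The narrative H-bond count (`hbonds_including_salt_bridges`)
follows the common convention of counting salt bridges among H-bond-type
contacts while still storing them under their own class. Pie fractions
exclude proximal records by default (they are non-interactions); a switch
includes them. Residue-level summaries count proximal-only pairs as pairs
in contact but never as directional interactions. Exports are TSV/JSON
with fixed precision (distances and areas 2 decimals, angles 1 decimal),
which makes repeated runs byte-identical; wall-clock timing lives only in
`provenance.json`.

## Synthetic fixtures

The generator plants one ideal-geometry instance of any class from frozen
energy-minimized residue templates (the ~10 amino acids the motifs use,
guanine, water, Mg²⁺ and a chlorobenzene-like het group carrying the
halogen — standard residues lack halogens). Partner residues approach
head-to-head along an assembly axis with bodies oriented away so only the
intended functional groups meet; defining distances sit at least ~0.2 Å
inside their thresholds so recovery is robust under the seeded random
rigid-body rotation + translation applied to the whole assembly. Fixtures
emulate geometry, not energetics: no force-field relaxation, no crystal
packing, no conformational strain, single side-chain rotamers. Passing the
closure tests therefore demonstrates that the detectors implement their
stated geometric definitions and are rigid-motion invariant — not that the
thresholds themselves are optimal for any particular crystal structure.

## Numerical choices and edge cases

Ring planes come from the SVD of centered ring coordinates; rings deviating
more than 0.35 Å from planarity are rejected with a warning, as are rings
with missing atoms. Degenerate hydrogen-placement geometry (collinear
parents) skips that hydrogen with a warning rather than failing. Boundary
comparisons are inclusive (d ≤ threshold). Angles between ring normals and
probe directions are folded to [0°, 90°] since normals are sign-ambiguous.
Empty interfaces produce a valid zero-pair report flagged in provenance.

## Known limitations

* No pKa or protonation-state prediction, no His/Asn/Gln flip
  optimization, no energy or binding-affinity estimates.
* Carbon-donor criteria without explicit hydrogens are necessarily
  heavy-atom approximations (a fixed ≥80° antecedent-angle filter stands
  in for C–H directionality).
* The published per-complex interaction censuses of reference interfaces
  depend on the exact thresholds of the original analyses; the defaults
  here are literature-standard values, and the worked-example checks run
  against them as the committed reference profile.
* mmCIF is read but not written; no biological-assembly expansion; waters
  and ligands cannot themselves be selected as partners (waters/metals
  mediate only).
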