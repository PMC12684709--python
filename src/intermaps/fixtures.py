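"""Synthetic two-chain PDB fixtures: one ideal-geometry instance of any
interaction class, with machine-readable ground truth.

Each motif places two template residues (chain A and chain B) head-to-head
along an assembly axis at the class's ideal distance, adds a mediator
(water/magnesium) when the class needs one, optionally writes an explicit
polar hydrogen aimed at the acceptor/ring, and finally applies a random
rigid-body rotation + translation controlled by the seed. Default
geometries sit strictly inside the default thresholds so the classifier
must recover exactly the planted class; stretching the defining distance
past the threshold is the negative control.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Residue, ResidueKey, Structure, write_pdb
from .templates import ELEMENT_OVERRIDES, TEMPLATES

__all__ = ["MotifSpec", "GroundTruth", "MOTIF_CLASSES", "make_motif",
           "make_mini_complex", "compare_report"]

RING = "__ring__"  # anchor sentinel: ring centroid / normal

# The 16 interaction classes a motif can plant, plus the clash and proximal
# control motifs.
MOTIF_CLASSES = (
    "hbond", "salt_bridge", "weak_hbond", "water_mediated", "metal_mediated",
    "disulfide", "halogen_bond", "pi_pi", "lone_pair_pi", "anion_pi",
    "cation_pi", "amino_pi", "onsh_pi", "ch_pi", "vdw_polar", "vdw_apolar",
    "clash", "proximal",
)

_PHE_RING = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


@dataclass
class _Placement:
    resname: str
    anchor: str          # atom name or RING
    parent: str | None   # atom defining the outward bond (None for RING)
    polar_deg: float     # angle of the anchor->parent bond from the +z axis
    azimuth_deg: float = 0.0  # spin about the assembly axis


@dataclass
class MotifSpec:
    klass: str
    distance: float | None = None      # override of the defining distance
    swap_partners: bool = False

    def __post_init__(self):
        if self.klass not in MOTIF_CLASSES:
            raise ValueError(f"unsupported motif class {self.klass!r}")
        if self.distance is not None and self.distance <= 0:
            raise ValueError("distance override must be positive")


@dataclass
class GroundTruth:
    """Expected classification, written alongside every generated fixture."""

    expected: list[dict] = field(default_factory=list)

    def to_json(self) -> list[dict]:
        return list(self.expected)


# motif table: placements for partner A and B, assembly distance, optional
# mediator z-positions, optional explicit hydrogens aimed along the axis,
# and the expected records (klass, atom1, atom2, mediator atom, clash)
_MOTIFS: dict[str, dict] = {
    "hbond": dict(
        A=_Placement("SER", "OG", "CB", 109.5),
        B=_Placement("ALA", "O", "C", 180.0), d=3.2,
        manual_h=[("A", "OG", "HG", 0.96, "partner")],
        expect=[("hbond", "OG", "O", None, False)]),
    "salt_bridge": dict(
        A=_Placement("ASP", "OD1", "CG", 150.0),
        B=_Placement("LYS", "NZ", "CE", 160.0), d=3.4,
        expect=[("salt_bridge", "OD1", "NZ", None, False)]),
    "weak_hbond": dict(
        A=_Placement("ALA", "CB", "CA", 180.0),
        B=_Placement("ALA", "O", "C", 180.0), d=3.4,
        expect=[("weak_hbond", "CB", "O", None, False)]),
    "water_mediated": dict(
        A=_Placement("SER", "OG", "CB", 109.5),
        B=_Placement("ASN", "OD1", "CG", 180.0), d=5.6, water=0.5,
        d_factor=2.0,  # the defining distance is the mediator leg (= d/2)
        expect=[("water_mediated", "OG", "OD1", "O", False)]),
    "metal_mediated": dict(
        A=_Placement("ASP", "OD1", "CG", 150.0),
        B=_Placement("GLU", "OE1", "CD", 150.0), d=4.2, metal=0.5,
        d_factor=2.0,
        expect=[("metal_mediated", "OD1", "OE1", "MG", False)]),
    "disulfide": dict(
        A=_Placement("CYS", "SG", "CB", 150.0),
        B=_Placement("CYS", "SG", "CB", 150.0), d=2.05,
        expect=[("disulfide", "SG", "SG", None, False)]),
    "halogen_bond": dict(
        A=_Placement("CLB", "CL", "C1", 180.0),
        B=_Placement("ALA", "O", "C", 180.0), d=3.30,
        expect=[("halogen_bond", "CL", "O", None, False)]),
    "pi_pi": dict(
        A=_Placement("PHE", RING, None, 180.0),
        B=_Placement("PHE", RING, None, 180.0, azimuth_deg=180.0), d=3.8,
        expect=[("pi_pi", "ring", "ring", None, False)]),
    "lone_pair_pi": dict(
        A=_Placement("SER", "OG", "CB", 130.0),
        B=_Placement("PHE", RING, None, 180.0), d=3.5,
        manual_h=[("A", "OG", "HG", 0.96, (-1.0, 0.0, 0.0))],
        expect=[("lone_pair_pi", "OG", "ring", None, False)]),
    "anion_pi": dict(
        A=_Placement("ASP", "OD1", "CG", 150.0),
        B=_Placement("PHE", RING, None, 180.0), d=4.0,
        expect=[("anion_pi", "OD1", "ring", None, False)]),
    "cation_pi": dict(
        A=_Placement("LYS", "NZ", "CE", 160.0),
        B=_Placement("PHE", RING, None, 180.0), d=4.5,
        expect=[("cation_pi", "NZ", "ring", None, False)]),
    "amino_pi": dict(
        A=_Placement("ASN", "ND2", "CG", 140.0),
        B=_Placement("PHE", RING, None, 180.0), d=3.8,
        expect=[("amino_pi", "ND2", "ring", None, False)]),
    "onsh_pi": dict(
        A=_Placement("SER", "OG", "CB", 109.5),
        B=_Placement("PHE", RING, None, 180.0), d=4.2,
        manual_h=[("A", "OG", "HG", 0.96, "partner")],
        expect=[("onsh_pi", "OG", "ring", None, False)]),
    "ch_pi": dict(
        A=_Placement("ALA", "CB", "CA", 180.0),
        B=_Placement("PHE", RING, None, 180.0), d=4.2,
        expect=[("ch_pi", "CB", "ring", None, False)]),
    "vdw_polar": dict(
        A=_Placement("ALA", "O", "C", 160.0),
        B=_Placement("ALA", "O", "C", 160.0), d=3.2,
        expect=[("vdw_polar", "O", "O", None, False)]),
    "vdw_apolar": dict(
        A=_Placement("ALA", "CB", "CA", 180.0),
        B=_Placement("ALA", "CB", "CA", 180.0), d=3.7,
        expect=[("vdw_apolar", "CB", "CB", None, False)]),
    "clash": dict(
        A=_Placement("SER", "OG", "CB", 140.0),
        B=_Placement("ALA", "O", "C", 180.0), d=2.6,
        manual_h=[("A", "OG", "HG", 0.96, "partner")],
        expect=[("hbond", "OG", "O", None, True)]),
    "proximal": dict(
        A=_Placement("ALA", "CB", "CA", 180.0),
        B=_Placement("ALA", "CB", "CA", 180.0), d=4.8,
        expect=[("proximal", "CB", "CB", None, False)]),
}

# the threshold each motif's defining distance is checked against (used by
# the negative-control stretch)
DEFINING_THRESHOLD = {
    "hbond": "hbond.da_max", "salt_bridge": "salt_bridge.max",
    "weak_hbond": "weak_hbond.ca_max", "water_mediated": "water_mediated.max",
    "metal_mediated": "metal_mediated.tight", "disulfide": "disulfide.max",
    "pi_pi": "pi_pi.max", "lone_pair_pi": "lone_pair_pi.max",
    "anion_pi": "anion_pi.max", "cation_pi": "cation_pi.max",
    "amino_pi": "amino_pi.max", "onsh_pi": "onsh_pi.h_max",
    "ch_pi": "ch_pi.heavy_max",
}


# ---------------------------------------------------------------------------
# geometry

def _unit(v):
    return v / np.linalg.norm(v)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # opposite: rotate pi about any perpendicular
        p = np.array([1.0, 0, 0])
        if abs(a[0]) > 0.9:
            p = np.array([0, 1.0, 0])
        axis = _unit(np.cross(a, p))
        return _axis_rotation(axis, math.pi)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_rotation(axis, math.atan2(s, c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C]])


def _template_coords(resname: str) -> dict[str, np.ndarray]:
    return {n: np.array(xyz) for n, xyz in TEMPLATES[resname].items()}


def _ring_frame(coords: dict[str, np.ndarray]
                ) -> tuple[np.ndarray, np.ndarray]:
    ring = np.array([coords[n] for n in _PHE_RING if n in coords])
    if len(ring) < 5:  # CLB ring
        ring = np.array([coords[f"C{i}"] for i in range(1, 7)])
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    _, _, vt = np.linalg.svd(centered)
    return centroid, _unit(vt[2])


def _place(placement: _Placement) -> dict[str, np.ndarray]:
    """Orient a template so its anchor sits at the origin and the
    anchor->parent bond makes ``polar_deg`` with the +z axis (the assembly
    axis pointing at the partner); deterministic spin."""
    coords = _template_coords(placement.resname)
    if placement.anchor == RING:
        anchor, normal = _ring_frame(coords)
        u = normal
    else:
        anchor = coords[placement.anchor]
        u = _unit(coords[placement.parent] - anchor)
    coords = {n: c - anchor for n, c in coords.items()}
    theta = math.radians(placement.polar_deg)
    target = np.array([math.sin(theta), 0.0, math.cos(theta)])
    R = _rotation_between(u, target)
    if placement.azimuth_deg:
        R = _axis_rotation(np.array([0.0, 0.0, 1.0]),
                           math.radians(placement.azimuth_deg)) @ R
    return {n: R @ c for n, c in coords.items()}


_FLIP = np.diag([1.0, -1.0, -1.0])  # rotate pi about x: local +z -> global -z


def _element_of(name: str) -> str:
    if name in ELEMENT_OVERRIDES:
        return ELEMENT_OVERRIDES[name]
    s = name.lstrip("0123456789")
    return "H" if s[:1] == "H" else s[:1]


def _random_rigid(seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    t = rng.uniform(-10.0, 10.0, size=3)
    return R, t


# ---------------------------------------------------------------------------
# assembly

def _build_motif(spec: MotifSpec, offset: np.ndarray
                 ) -> tuple[dict, list[tuple]]:
    """Returns {'A': (resname, {atom: coords}), 'B': ..., 'W': ..., 'M': ...}
    in assembly coordinates, plus the ground-truth tuples."""
    m = _MOTIFS[spec.klass]
    d = (spec.distance * m.get("d_factor", 1.0)
         if spec.distance is not None else m["d"])

    ca = _place(m["A"])
    cb_local = _place(m["B"])
    cb = {n: _FLIP @ c + np.array([0, 0, d]) for n, c in cb_local.items()}

    for side, atom, hname, bond, aim in m.get("manual_h", []):
        coords = ca if side == "A" else cb
        origin = coords[atom]
        if aim == "partner":
            target = np.array([0, 0, d if side == "A" else 0.0])
            direction = _unit(target - origin)
        else:
            direction = _unit(np.array(aim, dtype=float))
        coords[hname] = origin + bond * direction

    parts = {"A": (m["A"].resname, {n: c + offset for n, c in ca.items()}),
             "B": (m["B"].resname, {n: c + offset for n, c in cb.items()})}
    if "water" in m:
        parts["W"] = ("HOH", {"O": np.array([0, 0, d * m["water"]]) + offset})
    if "metal" in m:
        parts["M"] = ("MG", {"MG": np.array([0, 0, d * m["metal"]]) + offset})

    expect = []
    for klass, a1, a2, med, clash in m["expect"]:
        if spec.swap_partners:
            a1, a2 = a2, a1
        expect.append((klass, a1, a2, med, clash))
    return parts, expect


def _assemble(motifs: list[tuple[dict, list[tuple]]], seed: int
              ) -> tuple[str, GroundTruth]:
    R, t = _random_rigid(seed)
    chains: dict[str, list[Residue]] = {"A": [], "B": [], "W": [], "M": []}
    counters = {k: 0 for k in chains}
    serial = 0
    gt = GroundTruth()
    for parts, expect in motifs:
        numbers = {}
        for cid in ("A", "B", "W", "M"):
            if cid not in parts:
                continue
            resname, coords = parts[cid]
            counters[cid] += 1
            numbers[cid] = counters[cid]
            category = {"W": "water", "M": "metal-ion"}.get(cid)
            atoms = []
            for name, pos in coords.items():
                serial += 1
                atoms.append(Atom(serial=serial, name=name,
                                  element=_element_of(name),
                                  coords=R @ pos + t,
                                  is_hetero=cid in ("W", "M")
                                  or resname == "CLB"))
            if category is None:
                category = ("protein" if resname in
                            ("ALA", "GLY", "SER", "CYS", "ASP", "GLU", "ASN",
                             "LYS", "PHE") else "other-ligand")
            chains[cid].append(Residue(
                ResidueKey(cid, counters[cid], "", resname), category, atoms))
        for klass, a1, a2, med, clash in expect:
            gt.expected.append({
                "klass": klass,
                "chain1": "A", "resnum1": numbers["A"], "atom1": a1,
                "chain2": "B", "resnum2": numbers["B"], "atom2": a2,
                "mediator": med, "clash": clash})
    structure = Structure("FIXTURE", [(cid, residues) for cid, residues
                                      in chains.items() if residues], "pdb")
    return write_pdb(structure), gt


def make_motif(spec: MotifSpec | str, seed: int = 0) -> tuple[str, GroundTruth]:
    """One motif as PDB text plus its ground truth; the seed sets the random
    rigid-body orientation of the whole assembly."""
    if isinstance(spec, str):
        spec = MotifSpec(spec)
    return _assemble([_build_motif(spec, np.zeros(3))], seed)


def make_mini_complex(n_motifs: int, seed: int = 0,
                      classes: list[str] | None = None
                      ) -> tuple[str, GroundTruth]:
    """n_motifs motifs, spatially separated by 25 A so the planted
    interactions cannot interfere, merged into one two-chain complex."""
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if classes is None:
        classes = [c for c in MOTIF_CLASSES
                   if c not in ("clash", "proximal")]
    picked = [classes[i % len(classes)] for i in range(n_motifs)]
    motifs = []
    for i, klass in enumerate(picked):
        offset = np.array([25.0 * i, 0.0, 0.0])
        motifs.append(_build_motif(MotifSpec(klass), offset))
    return _assemble(motifs, seed)


# ---------------------------------------------------------------------------
# ground-truth comparison

def _norm_atom(name: str) -> str:
    return "ring" if name.startswith("ring(") else name


def report_signature(report) -> list[tuple]:
    """Multiset signature of a report's interactions for ground-truth
    comparison (ring labels collapsed to 'ring')."""
    sig = []
    for ia in report.interactions():
        sig.append((ia.klass, ia.res1.chain_id, ia.res1.seq_number,
                    _norm_atom(ia.atom1), ia.res2.chain_id,
                    ia.res2.seq_number, _norm_atom(ia.atom2),
                    ia.mediator[1] if ia.mediator else None, ia.clash))
    return sorted(sig)


def compare_report(gt: GroundTruth, report) -> tuple[list, list]:
    """(missing, extra) between ground truth and a classified report."""
    from collections import Counter
    want = Counter((e["klass"], e["chain1"], e["resnum1"], e["atom1"],
                    e["chain2"], e["resnum2"], e["atom2"], e["mediator"],
                    e["clash"]) for e in gt.expected)
    got = Counter(report_signature(report))
    missing = sorted((want - got).elements())
    extra = sorted((got - want).elements())
    return missing, extra
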