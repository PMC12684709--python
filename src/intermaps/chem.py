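"""Per-atom chemistry annotation, aromatic-ring detection and polar-hydrogen
placement.

The tables (van der Waals radii, donor/acceptor atom sets, charge groups,
ring definitions) live in ``data/chem_tables.yaml`` and can be overridden by
the user; unknown residues fall back to element-level rules so annotation is
a total function over any parsed structure.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .structure import Atom, Residue, ResidueKey, Structure

log = logging.getLogger(__name__)

__all__ = ["AtomAnnotation", "RingSystem", "ChemTables", "annotate",
           "find_rings", "place_polar_hydrogens"]

COVALENT_H_MAX = 1.5  # Angstrom; H closer than this to a heavy atom is bonded
PEPTIDE_BOND_MAX = 2.0
RING_PLANARITY_MAX = 0.35

NH_BOND = 1.01
OH_BOND = 0.96
SH_BOND = 1.34


@dataclass
class AtomAnnotation:
    vdw_radius: float
    polarity: str  # polar | apolar
    is_donor_heavy: bool = False
    is_acceptor: bool = False
    charge_group: str = "neutral"  # anionic | cationic | neutral
    is_halogen: bool = False
    is_metal: bool = False
    is_water_oxygen: bool = False
    is_amino_pi: bool = False
    is_weak_donor_carbon: bool = False
    attached_hydrogens: list[Atom] = field(default_factory=list)
    unknown_residue: bool = False


@dataclass
class RingSystem:
    residue: ResidueKey
    ring_atoms: list[str]
    atoms: list[Atom]
    centroid: np.ndarray
    normal: np.ndarray
    ring_kind: str  # aromatic-5 | aromatic-6


@dataclass
class ChemTables:
    """Consolidated per-atom chemistry lookup tables."""

    vdw_radii: dict[str, float]
    donors: dict[str, list[str]]
    acceptors: dict[str, list[str]]
    cationic_groups: dict[str, list[list[str]]]
    anionic_groups: dict[str, list[list[str]]]
    rings: dict[str, list[list[str]]]
    amino_pi_groups: dict[str, list[str]]
    carbons_without_h: dict[str, list[str]]
    metal_elements: set[str]
    halogen_elements: set[str]

    _default: "ChemTables | None" = None

    @classmethod
    def from_mapping(cls, raw: dict) -> "ChemTables":
        return cls(
            vdw_radii={str(k): float(v) for k, v in raw["vdw_radii"].items()},
            donors={k: list(v) for k, v in raw["donors"].items()},
            acceptors={k: list(v) for k, v in raw["acceptors"].items()},
            cationic_groups={k: [list(g) for g in v]
                             for k, v in raw["cationic_groups"].items()},
            anionic_groups={k: [list(g) for g in v]
                            for k, v in raw["anionic_groups"].items()},
            rings={k: [list(g) for g in v] for k, v in raw["rings"].items()},
            amino_pi_groups={k: list(v) for k, v in raw["amino_pi_groups"].items()},
            carbons_without_h={k: list(v)
                               for k, v in raw["carbons_without_h"].items()},
            metal_elements={str(e) for e in raw["metal_elements"]},
            halogen_elements={str(e) for e in raw["halogen_elements"]},
        )

    @classmethod
    def from_file(cls, path) -> "ChemTables":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ChemTables":
        if cls._default is None:
            text = resources.files("intermaps.data").joinpath(
                "chem_tables.yaml").read_text()
            cls._default = cls.from_mapping(yaml.safe_load(text))
        return cls._default

    def vdw(self, element: str) -> float:
        el = element.capitalize() if len(element) > 1 else element.upper()
        return self.vdw_radii.get(el, self.vdw_radii.get(element,
                                  self.vdw_radii["default"]))


def _norm_el(element: str) -> str:
    return element.capitalize() if len(element) > 1 else element.upper()


def _attached_h(res: Residue, heavy: Atom) -> list[Atom]:
    return [a for a in res.atoms
            if a.is_hydrogen
            and float(np.linalg.norm(a.coords - heavy.coords)) < COVALENT_H_MAX]


def _lookup(table: dict[str, list[str]], res: Residue, extra_keys=()) -> set[str]:
    names: set[str] = set(table.get(res.key.residue_name, []))
    for k in extra_keys:
        names |= set(table.get(k, []))
    return names


def annotate(structure: Structure,
             tables: ChemTables | None = None) -> dict[Atom, AtomAnnotation]:
    """Assign chemistry to every atom of the structure.

    Returns a map keyed by atom object. Recognized standard residues get
    table-driven roles; unknown het groups fall back to element-level rules
    (N/O polar, C/S apolar, element radius) and are flagged.
    """
    tables = tables or ChemTables.default()
    out: dict[Atom, AtomAnnotation] = {}
    for cid, residues in structure.chains:
        for i, res in enumerate(residues):
            resname = res.key.residue_name
            known = (res.category in ("water", "metal-ion")
                     or resname in tables.donors or resname in tables.acceptors
                     or resname in tables.rings
                     or res.category in ("protein", "dna", "rna"))
            extra_don, extra_acc, extra_cwh = [], [], []
            if res.category == "protein":
                extra_acc.append("_protein_backbone")
                extra_cwh.append("_protein_backbone")
                if resname != "PRO":
                    extra_don.append("_protein_backbone")
            if res.category in ("dna", "rna"):
                extra_acc.append("_nucleic_backbone")
            donors = _lookup(tables.donors, res, extra_don)
            acceptors = _lookup(tables.acceptors, res, extra_acc)
            no_h_carbons = _lookup(tables.carbons_without_h, res, extra_cwh)

            cation_atoms: set[str] = set()
            for group in tables.cationic_groups.get(resname, []):
                cation_atoms |= set(group)
            anion_atoms: set[str] = set()
            for group in tables.anionic_groups.get(resname, []):
                anion_atoms |= set(group)
            if res.category in ("dna", "rna"):
                for group in tables.anionic_groups.get("_nucleic_phosphate", []):
                    anion_atoms |= set(group)
            # terminal groups, detected geometrically
            if res.category == "protein":
                if _is_n_terminal(residues, i):
                    cation_atoms.add("N")
                if res.atom("OXT") is not None:
                    anion_atoms |= {"O", "OXT"}
            amino_pi = set(tables.amino_pi_groups.get(resname, []))

            for a in res.atoms:
                el = _norm_el(a.element)
                hs = _attached_h(res, a) if el != "H" else []
                polar = el in ("N", "O") or (
                    el == "H" and _parent_is_polar(res, a))
                is_metal = (res.category == "metal-ion"
                            and el in tables.metal_elements)
                ann = AtomAnnotation(
                    vdw_radius=tables.vdw(el),
                    polarity="polar" if polar else "apolar",
                    is_donor_heavy=(a.name in donors and el in ("N", "O", "S")),
                    is_acceptor=a.name in acceptors,
                    charge_group=("cationic" if a.name in cation_atoms
                                  else "anionic" if a.name in anion_atoms
                                  else "neutral"),
                    is_halogen=el in tables.halogen_elements,
                    is_metal=is_metal,
                    is_water_oxygen=(res.category == "water" and el == "O"),
                    is_amino_pi=a.name in amino_pi,
                    is_weak_donor_carbon=(el == "C" and a.name not in no_h_carbons),
                    attached_hydrogens=hs,
                    unknown_residue=not known,
                )
                if not known and el in ("N", "O", "S") and hs:
                    ann.is_donor_heavy = True  # explicit H on unknown group
                if not known and el in ("N", "O"):
                    ann.is_acceptor = True
                out[a] = ann
            if not known:
                log.warning("unknown residue %s annotated by element-level "
                            "fallback", res.key)
    return out


def _parent_is_polar(res: Residue, h: Atom) -> bool:
    for a in res.atoms:
        if a.is_hydrogen or a is h:
            continue
        if float(np.linalg.norm(a.coords - h.coords)) < COVALENT_H_MAX:
            return _norm_el(a.element) in ("N", "O")
    return False


def _is_n_terminal(residues: list[Residue], idx: int) -> bool:
    res = residues[idx]
    n = res.atom("N")
    if n is None or res.category != "protein":
        return False
    for j in range(idx - 1, -1, -1):
        prev = residues[j]
        if prev.category != "protein":
            continue
        c = prev.atom("C")
        if c is not None and np.linalg.norm(c.coords - n.coords) < PEPTIDE_BOND_MAX:
            return False
        break
    return True


def _prev_c(residues: list[Residue], idx: int) -> Atom | None:
    n = residues[idx].atom("N")
    if n is None:
        return None
    for j in range(idx - 1, -1, -1):
        prev = residues[j]
        if not prev.is_polymer:
            continue
        c = prev.atom("C")
        if c is not None and np.linalg.norm(c.coords - n.coords) < PEPTIDE_BOND_MAX:
            return c
        break
    return None


# ---------------------------------------------------------------------------
# aromatic rings

def find_rings(structure: Structure,
               tables: ChemTables | None = None) -> list[RingSystem]:
    """Locate every defined aromatic ring with all member atoms present.

    The centroid is the unweighted mean of the ring atoms; the normal is the
    smallest-singular-vector of the centered coordinates (unit length). Rings
    deviating from planarity by more than 0.35 A are rejected with a warning.
    """
    tables = tables or ChemTables.default()
    rings: list[RingSystem] = []
    for res in structure.residues():
        for ring_names in tables.rings.get(res.key.residue_name, []):
            atoms = [res.atom(n) for n in ring_names]
            if any(a is None for a in atoms):
                log.warning("ring %s in %s skipped: missing atoms",
                            ring_names, res.key)
                continue
            coords = np.array([a.coords for a in atoms])
            centroid = coords.mean(axis=0)
            centered = coords - centroid
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            normal = vt[2]
            dev = np.abs(centered @ normal).max()
            if dev > RING_PLANARITY_MAX:
                log.warning("ring %s in %s rejected: planarity deviation "
                            "%.2f A", ring_names, res.key, dev)
                continue
            rings.append(RingSystem(
                residue=res.key, ring_atoms=list(ring_names), atoms=atoms,
                centroid=centroid, normal=normal / np.linalg.norm(normal),
                ring_kind=f"aromatic-{len(ring_names)}"))
    return rings


# ---------------------------------------------------------------------------
# polar hydrogen placement

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def _sp2_bisector_h(n: np.ndarray, a: np.ndarray, b: np.ndarray,
                    bond: float) -> np.ndarray:
    """H anti to the bisector of the two heavy neighbors (planar N-H)."""
    d = _unit(_unit(n - a) + _unit(n - b))
    return n + bond * d


def _sp2_amide_h2(n: np.ndarray, c: np.ndarray, ref: np.ndarray,
                  bond: float) -> list[np.ndarray]:
    """Two H on an sp2 NH2 group, in the (N, C, ref) plane, 120 deg from N-C."""
    w = _unit(c - n)
    axis = np.cross(w, ref - c)
    if np.linalg.norm(axis) < 1e-6:  # degenerate reference: any perpendicular
        axis = np.cross(w, np.array([1.0, 0, 0]))
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(w, np.array([0, 1.0, 0]))
    p = _unit(np.cross(_unit(axis), w))
    c120, s120 = math.cos(math.radians(120)), math.sin(math.radians(120))
    return [n + bond * (c120 * w + s120 * p), n + bond * (c120 * w - s120 * p)]


def _frame(axis: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (p, q) spanning the plane perpendicular to axis, with p in
    the (axis, ref) plane."""
    a = _unit(axis)
    r = ref - np.dot(ref, a) * a
    if np.linalg.norm(r) < 1e-6:
        r = np.array([1.0, 0, 0]) - a[0] * a
        if np.linalg.norm(r) < 1e-6:
            r = np.array([0, 1.0, 0]) - a[1] * a
    p = _unit(r)
    return p, np.cross(a, p)


def _tetra_h(n: np.ndarray, parent: np.ndarray, stagger_ref: np.ndarray,
             bond: float, count: int, phi0: float = math.pi) -> list[np.ndarray]:
    """1-3 hydrogens on an sp3 N/O, 109.5 deg from the parent bond, staggered
    (phi0=pi puts the first H anti to the staggering reference)."""
    a = _unit(parent - n)  # from N towards parent
    theta = math.radians(109.5)
    p, q = _frame(a, stagger_ref - parent)
    out = []
    for k in range(count):
        phi = phi0 + 2 * math.pi * k / 3
        d = math.cos(theta) * a + math.sin(theta) * (math.cos(phi) * p
                                                     + math.sin(phi) * q)
        out.append(n + bond * d)
    return out


def _hydroxyl_h(o: np.ndarray, parent: np.ndarray, stagger_ref: np.ndarray,
                acceptors: list[np.ndarray], bond: float = OH_BOND,
                max_acc_dist: float = 3.5) -> np.ndarray:
    """Rotatable O-H: orient toward the nearest acceptor within reach, else
    use the staggered default (anti to the parent's other substituent)."""
    a = _unit(parent - o)
    theta = math.radians(109.5)
    p, q = _frame(a, stagger_ref - parent)
    target = None
    best = max_acc_dist
    for acc in acceptors:
        d = float(np.linalg.norm(acc - o))
        if 0.1 < d < best:
            best, target = d, acc
    if target is None:
        phi = math.pi
    else:
        v = target - o
        phi = math.atan2(float(np.dot(v, q)), float(np.dot(v, p)))
    d = math.cos(theta) * a + math.sin(theta) * (math.cos(phi) * p
                                                 + math.sin(phi) * q)
    return o + bond * d


_SP2_NH1 = {  # residue -> heavy atom -> (neighbor_a, neighbor_b, H name)
    "ARG": {"NE": ("CD", "CZ", "HE")},
    "TRP": {"NE1": ("CD1", "CE2", "HE1")},
    "HIS": {"ND1": ("CG", "CE1", "HD1"), "NE2": ("CD2", "CE1", "HE2")},
    "G": {"N1": ("C2", "C6", "H1")},
    "DG": {"N1": ("C2", "C6", "H1")},
    "U": {"N3": ("C2", "C4", "H3")},
    "DT": {"N3": ("C2", "C4", "H3")},
}

_SP2_NH2 = {  # residue -> N -> (parent C, in-plane reference, H names)
    "ARG": {"NH1": ("CZ", "NE", ("HH11", "HH12")),
            "NH2": ("CZ", "NE", ("HH21", "HH22"))},
    "ASN": {"ND2": ("CG", "OD1", ("HD21", "HD22"))},
    "GLN": {"NE2": ("CD", "OE1", ("HE21", "HE22"))},
    "A": {"N6": ("C6", "N1", ("H61", "H62"))},
    "DA": {"N6": ("C6", "N1", ("H61", "H62"))},
    "G": {"N2": ("C2", "N1", ("H21", "H22"))},
    "DG": {"N2": ("C2", "N1", ("H21", "H22"))},
    "C": {"N4": ("C4", "N3", ("H41", "H42"))},
    "DC": {"N4": ("C4", "N3", ("H41", "H42"))},
}

_HYDROXYL = {  # residue -> O -> (parent, stagger reference, H name, bond)
    "SER": {"OG": ("CB", "CA", "HG", OH_BOND)},
    "THR": {"OG1": ("CB", "CA", "HG1", OH_BOND)},
    "TYR": {"OH": ("CZ", "CE1", "HH", OH_BOND)},
    "CYS": {"SG": ("CB", "CA", "HG", SH_BOND)},
}
_SUGAR_OH = {"O2'": ("C2'", "C1'", "HO2'", OH_BOND)}


def place_polar_hydrogens(structure: Structure,
                          tables: ChemTables | None = None,
                          annotations: dict[Atom, AtomAnnotation] | None = None,
                          ) -> Structure:
    """Append ideal-geometry polar hydrogens (N-H 1.01 A, O-H 0.96 A).

    Residues that already contain any hydrogen are left untouched, so the
    operation is idempotent. Existing atoms are never moved. Rotatable
    hydroxyls point at the nearest acceptor within 3.5 A when one exists.
    """
    tables = tables or ChemTables.default()
    annotations = annotations or annotate(structure, tables)

    acceptor_coords = [a.coords for a, ann in annotations.items()
                       if ann.is_acceptor and not a.is_hydrogen]

    serial = max((a.serial for a in structure.atoms()), default=0)
    new_chains: list[tuple[str, list[Residue]]] = []
    for cid, residues in structure.chains:
        new_residues: list[Residue] = []
        for i, res in enumerate(residues):
            new_res = Residue(res.key, res.category, list(res.atoms))
            new_residues.append(new_res)
            if res.category in ("water", "metal-ion") or not res.is_polymer:
                continue
            if any(a.is_hydrogen for a in res.atoms):
                continue  # trust and keep existing hydrogens

            def emit(name: str, pos: np.ndarray):
                nonlocal serial
                serial += 1
                new_res.atoms.append(Atom(serial=serial, name=name,
                                          element="H", coords=pos,
                                          is_hetero=res.atoms[0].is_hetero))

            resname = res.key.residue_name
            try:
                _place_for_residue(res, residues, i, resname, emit,
                                   acceptor_coords)
            except ValueError as exc:  # degenerate parent geometry
                log.warning("hydrogen placement skipped for %s: %s",
                            res.key, exc)
        new_chains.append((cid, new_residues))
    return Structure(structure.entry_id, new_chains, structure.source_format)


def _place_for_residue(res: Residue, residues: list[Residue], idx: int,
                       resname: str, emit, acceptor_coords) -> None:
    get = res.atom

    # backbone amide H (protein, not proline, not N-terminal)
    if res.category == "protein" and resname != "PRO":
        n, ca = get("N"), get("CA")
        c_prev = _prev_c(residues, idx)
        if n is not None and ca is not None:
            if c_prev is not None:
                emit("H", _sp2_bisector_h(n.coords, c_prev.coords, ca.coords,
                                          NH_BOND))
            else:
                cb_or_c = get("C")
                if cb_or_c is not None:  # N-terminal ammonium, 3 H staggered
                    for k, pos in enumerate(_tetra_h(
                            n.coords, ca.coords, cb_or_c.coords, NH_BOND, 3), 1):
                        emit(f"H{k}", pos)

    for heavy_name, (na, nb, hname) in _SP2_NH1.get(resname, {}).items():
        h, a, b = get(heavy_name), get(na), get(nb)
        if h is not None and a is not None and b is not None:
            emit(hname, _sp2_bisector_h(h.coords, a.coords, b.coords, NH_BOND))

    for heavy_name, (cpar, ref, hnames) in _SP2_NH2.get(resname, {}).items():
        nat, cat, rat = get(heavy_name), get(cpar), get(ref)
        if nat is not None and cat is not None and rat is not None:
            for hname, pos in zip(hnames, _sp2_amide_h2(
                    nat.coords, cat.coords, rat.coords, NH_BOND)):
                emit(hname, pos)

    if resname == "LYS":
        nz, ce, cd = get("NZ"), get("CE"), get("CD")
        if nz is not None and ce is not None and cd is not None:
            for k, pos in enumerate(_tetra_h(nz.coords, ce.coords, cd.coords,
                                             NH_BOND, 3), 1):
                emit(f"HZ{k}", pos)

    hydroxyls = dict(_HYDROXYL.get(resname, {}))
    if res.category == "rna":
        hydroxyls.update(_SUGAR_OH)
    for oname, (pname, sname, hname, bond) in hydroxyls.items():
        o, par, sref = get(oname), get(pname), get(sname)
        if o is not None and par is not None and sref is not None:
            others = [c for c in acceptor_coords
                      if np.linalg.norm(c - o.coords) > 0.1]
            emit(hname, _hydroxyl_h(o.coords, par.coords, sref.coords,
                                    others, bond=bond))
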