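"""Detection and classification of inter-partner atomic interactions.

Sixteen interaction classes are recognized: hydrogen bonds, salt bridges,
weak (C-H) hydrogen bonds, water- and metal-mediated contacts, disulfide
bonds, halogen bonds, the seven-member pi family (pi-pi, lone pair-pi,
anion-pi, cation-pi, amino-pi, O/N/S-H-pi, C-H-pi) and polar/apolar van der
Waals contacts. Atom pairs closer than the sum of their van der Waals radii
are flagged as clashes (the class, when one applies, is kept and marked with
an asterisk in reports). Residue pairs inside the contact cutoff with no
classified atomic interaction are reported as 'proximal'.

Every detector is a pure geometric predicate over annotated atoms; a single
resolution pass afterwards applies the class precedence so each direct atom
pair yields at most one non-mediated record. Mediated (water/metal) records
are additional and unlimited.
"""
from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .chem import (AtomAnnotation, ChemTables, RingSystem, annotate,
                   find_rings, place_polar_hydrogens)
from .config import GeometryConfig
from .structure import (Atom, PartnerSelection, Residue, ResidueKey,
                        Structure, select_partners)

log = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_CLASSES", "DIRECTIONAL_CLASSES", "AtomicInteraction",
    "ResiduePairContact", "InterfaceReport", "residue_contacts",
    "classify_interface", "InteractionEngine",
]

# the 16 named classes + proximal; "clash" is a flag, not a class
INTERACTION_CLASSES = (
    "hbond", "salt_bridge", "weak_hbond", "water_mediated", "metal_mediated",
    "disulfide", "halogen_bond", "pi_pi", "lone_pair_pi", "anion_pi",
    "cation_pi", "amino_pi", "onsh_pi", "ch_pi", "vdw_polar", "vdw_apolar",
    "proximal",
)
NON_DIRECTIONAL = {"vdw_polar", "vdw_apolar", "proximal"}
DIRECTIONAL_CLASSES = tuple(c for c in INTERACTION_CLASSES
                            if c not in NON_DIRECTIONAL)

# exclusivity precedence (lower = stronger); all pi subclasses share a rank,
# their internal precedence is applied inside the pi detector
_RANK = {"disulfide": 0, "salt_bridge": 1, "hbond": 2, "halogen_bond": 3,
         "weak_hbond": 4, "pi_pi": 5, "cation_pi": 5, "anion_pi": 5,
         "lone_pair_pi": 5, "amino_pi": 5, "onsh_pi": 5, "ch_pi": 5,
         "vdw_polar": 6, "vdw_apolar": 6}

_PI_PROBE_ORDER = ("cation_pi", "anion_pi", "lone_pair_pi", "amino_pi",
                   "onsh_pi", "ch_pi")

TIGHT_METALS = {"Mg", "Zn", "Mn", "Fe", "Co", "Ni", "Cu", "Cd"}
COVALENT_MAX = 1.9  # heavy-heavy covalent neighbor search within a residue


@dataclass
class AtomicInteraction:
    """One classified inter-partner contact.

    ``atom1`` always belongs to partner 1 and ``atom2`` to partner 2.
    ``distance`` is the class's defining distance (donor-acceptor for
    H-bonds, centroid distances for the pi family, the longer leg for
    mediated contacts).
    """

    klass: str
    res1: ResidueKey
    res2: ResidueKey
    atom1: str
    atom2: str
    distance: float
    angle: float | None = None
    mediator: tuple[ResidueKey, str] | None = None
    mediator_legs: tuple[float, float] | None = None
    clash: bool = False
    # internal: direct atom pairs represented by this record (suppressed
    # from vdW re-reporting); ids of Atom objects
    covered: frozenset = field(default_factory=frozenset, repr=False,
                               compare=False)

    @property
    def directional(self) -> bool:
        return self.klass not in NON_DIRECTIONAL

    def label(self) -> str:
        return self.klass + ("*" if self.clash else "")


@dataclass
class ResiduePairContact:
    res1: ResidueKey
    res2: ResidueKey
    min_distance: float
    interactions: list[AtomicInteraction] = field(default_factory=list)


@dataclass
class InterfaceReport:
    selection: PartnerSelection
    config: GeometryConfig
    pairs: list[ResiduePairContact]
    sasa: "object | None" = None  # SASAResult, attached by the orchestrator
    provenance: dict = field(default_factory=dict)

    def interactions(self) -> Iterable[AtomicInteraction]:
        for p in self.pairs:
            yield from p.interactions

    def by_class(self) -> dict[str, list[AtomicInteraction]]:
        out: dict[str, list[AtomicInteraction]] = {c: [] for c in
                                                   INTERACTION_CLASSES}
        for ia in self.interactions():
            out[ia.klass].append(ia)
        return out


# ---------------------------------------------------------------------------
# geometry helpers

def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosv = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _axial_angle(normal: np.ndarray, centroid: np.ndarray,
                 point: np.ndarray) -> float:
    """Angle between the ring normal and centroid->point, folded to [0, 90]."""
    v = point - centroid
    n = np.linalg.norm(v)
    if n < 1e-9:
        return 0.0
    cosv = abs(float(np.dot(normal, v) / n))
    return math.degrees(math.acos(min(1.0, cosv)))


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosv = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, cosv)))


def _pair_key(a: Atom, b: Atom) -> tuple[int, int]:
    return (id(a), id(b))


# ---------------------------------------------------------------------------
# engine context

class _Side:
    """Pre-indexed atoms of one partner."""

    def __init__(self, residues: list[Residue]):
        self.residues = residues
        self.atoms: list[Atom] = [a for r in residues for a in r.atoms]
        self.heavy: list[Atom] = [a for a in self.atoms if not a.is_hydrogen]
        self.heavy_coords = (np.array([a.coords for a in self.heavy])
                             if self.heavy else np.empty((0, 3)))
        self.tree = cKDTree(self.heavy_coords) if self.heavy else None


class InteractionEngine:
    """Holds the annotated structure and runs all detectors.

    Construct once per (structure, selection, config); the individual
    ``detect_*`` methods are pure and can be called independently (the test
    suite exercises them against brute-force oracles), while
    :meth:`classify` applies precedence, vdW/clash handling and the proximal
    fallback.
    """

    def __init__(self, structure: Structure, selection: PartnerSelection,
                 config: GeometryConfig | None = None,
                 tables: ChemTables | None = None):
        self.config = config or GeometryConfig()
        self.tables = tables or ChemTables.default()

        if (self.config.hydrogen_mode == "explicit"
                and self.config.switches.get("place_hydrogens", True)):
            structure = place_polar_hydrogens(structure, self.tables)
            selection = select_partners(structure, selection.partner1,
                                        selection.partner2, selection.labels)
        self.structure = structure
        self.selection = selection
        self.ann = annotate(structure, self.tables)
        self.rings = find_rings(structure, self.tables)

        self.side1 = _Side(selection.residues1)
        self.side2 = _Side(selection.residues2)
        self.atom_res: dict[Atom, Residue] = {}
        self.atom_side: dict[Atom, int] = {}
        for side_no, side in ((1, self.side1), (2, self.side2)):
            for r in side.residues:
                for a in r.atoms:
                    self.atom_res[a] = r
                    self.atom_side[a] = side_no
        for r in structure.residues():
            for a in r.atoms:
                self.atom_res.setdefault(a, r)

        self.ring_side = {id(rs): selection.side_of(rs.residue)
                          for rs in self.rings}

    # -- small helpers ----------------------------------------------------

    def _res(self, a: Atom) -> Residue:
        return self.atom_res[a]

    def _key(self, a: Atom) -> ResidueKey:
        return self.atom_res[a].key

    def _neighbors(self, a: Atom) -> list[Atom]:
        """Covalently bonded heavy atoms within the same residue (and the
        peptide/phosphodiester link is irrelevant for our angle surrogates)."""
        res = self._res(a)
        return [b for b in res.atoms
                if b is not a and not b.is_hydrogen
                and np.linalg.norm(b.coords - a.coords) < COVALENT_MAX]

    def _cross_heavy_pairs(self, cutoff: float
                           ) -> list[tuple[Atom, Atom, float]]:
        if self.side1.tree is None or self.side2.tree is None:
            return []
        hits = self.side1.tree.query_ball_tree(self.side2.tree, r=cutoff)
        out = []
        for i, js in enumerate(hits):
            a = self.side1.heavy[i]
            for j in js:
                b = self.side2.heavy[j]
                d = float(np.linalg.norm(a.coords - b.coords))
                if d <= cutoff:
                    out.append((a, b, d))
        return out

    def _oriented(self, a: Atom, b: Atom) -> tuple[Atom, Atom]:
        """Order so the first atom is on partner 1."""
        return (a, b) if self.atom_side[a] == 1 else (b, a)

    def _mk(self, klass, a1, a2, distance, angle=None, mediator=None,
            legs=None, covered=()) -> AtomicInteraction:
        a1, a2 = self._oriented(a1, a2)
        cov = set(covered) or {_pair_key(a1, a2)}
        return AtomicInteraction(
            klass=klass, res1=self._key(a1), res2=self._key(a2),
            atom1=a1.name, atom2=a2.name, distance=distance, angle=angle,
            mediator=mediator, mediator_legs=legs, covered=frozenset(cov))

    # -- residue-level contact enumeration --------------------------------

    def residue_contacts(self) -> list[tuple[ResidueKey, ResidueKey, float]]:
        """Inter-partner residue pairs whose minimum heavy-atom distance is
        within the residue cutoff (all-atom when the config switch says so)."""
        cutoff = self.config.residue_cutoff
        heavy_only = self.config.switches["heavy_atoms_only_cutoff"]
        if heavy_only:
            pairs = self._cross_heavy_pairs(cutoff)
        else:
            from .structure import neighbor_atom_pairs
            pairs = neighbor_atom_pairs(self.side1.atoms, self.side2.atoms,
                                        cutoff)
        best: dict[tuple[ResidueKey, ResidueKey], float] = {}
        for a, b, d in pairs:
            k = (self._key(a), self._key(b))
            if d < best.get(k, math.inf):
                best[k] = d
        return sorted(((r1, r2, d) for (r1, r2), d in best.items()),
                      key=lambda t: (t[0], t[1]))

    # -- hydrogen bonds ----------------------------------------------------

    def _hbond_geometry_ok(self, don: Atom, acc: Atom, d_da: float
                           ) -> tuple[bool, float | None]:
        cfg = self.config
        if d_da > cfg["hbond.da_max"]:
            return False, None
        hs = self.ann[don].attached_hydrogens
        if cfg.hydrogen_mode == "explicit" and hs:
            best = None
            for h in hs:
                d_ha = float(np.linalg.norm(h.coords - acc.coords))
                ang = _angle(don.coords, h.coords, acc.coords)
                if d_ha <= cfg["hbond.ha_max"] and ang >= cfg["hbond.dha_min"]:
                    if best is None or ang > best:
                        best = ang
            return (best is not None), best
        # heavy-atom surrogate: donor-antecedent angle opens toward acceptor
        for c in self._neighbors(don):
            if _angle(c.coords, don.coords, acc.coords) >= cfg["hbond.cda_min"]:
                return True, None
        return not self._neighbors(don), None

    def detect_hbonds(self) -> list[AtomicInteraction]:
        cfg = self.config
        out = []
        for a, b, d in self._cross_heavy_pairs(cfg["hbond.da_max"]):
            for don, acc in ((a, b), (b, a)):
                if not (self.ann[don].is_donor_heavy
                        and self.ann[acc].is_acceptor):
                    continue
                ok, ang = self._hbond_geometry_ok(don, acc, d)
                if ok:
                    cov = {_pair_key(*self._oriented(don, acc))}
                    out.append(self._mk("hbond", don, acc, d, ang,
                                        covered=cov))
        return _dedup_pairs(out)

    # -- salt bridges ------------------------------------------------------

    def _charge_groups(self, residues: list[Residue], kind: str
                       ) -> list[tuple[Residue, list[Atom]]]:
        table = (self.tables.cationic_groups if kind == "cationic"
                 else self.tables.anionic_groups)
        his_ok = self.config.switches["his_cationic"]
        groups = []
        for res in residues:
            name = res.key.residue_name
            defs = list(table.get(name, []))
            if kind == "cationic" and name == "HIS" and not his_ok:
                defs = []
            if kind == "anionic" and res.category in ("dna", "rna"):
                defs += table.get("_nucleic_phosphate", [])
            for g in defs:
                atoms = [res.atom(n) for n in g]
                atoms = [x for x in atoms if x is not None]
                if atoms:
                    groups.append((res, atoms))
            # terminal groups flagged during annotation
            extra = [a for a in res.heavy_atoms()
                     if self.ann[a].charge_group == kind
                     and all(a not in g for _, g in groups)]
            if extra:
                groups.append((res, extra))
        return groups

    def detect_salt_bridges(self) -> list[AtomicInteraction]:
        """Group-level ionic contacts: one record per anionic/cationic group
        pair whose closest O/N-N distance is within the threshold."""
        cfg = self.config
        out = []
        for s_an, s_cat in ((self.side1, self.side2), (self.side2, self.side1)):
            anions = self._charge_groups(s_an.residues, "anionic")
            cations = self._charge_groups(s_cat.residues, "cationic")
            for res_a, g_a in anions:
                for res_c, g_c in cations:
                    best, pair = math.inf, None
                    for x in g_a:
                        if x.element not in ("O", "N"):
                            continue
                        for y in g_c:
                            if y.element != "N":
                                continue
                            d = float(np.linalg.norm(x.coords - y.coords))
                            if d < best:
                                best, pair = d, (x, y)
                    if pair is None or best > cfg["salt_bridge.max"]:
                        continue
                    if cfg.switches["salt_bridge_requires_hbond"]:
                        ok = any(
                            self._hbond_geometry_ok(
                                y, x, float(np.linalg.norm(x.coords - y.coords))
                            )[0]
                            for x in g_a for y in g_c
                            if self.ann[y].is_donor_heavy)
                        if not ok:
                            continue
                    cov = {_pair_key(*self._oriented(x, y))
                           for x in g_a for y in g_c
                           if np.linalg.norm(x.coords - y.coords)
                           <= cfg["salt_bridge.max"]}
                    out.append(self._mk("salt_bridge", pair[0], pair[1], best,
                                        covered=cov))
        return out

    # -- weak (C-H) hydrogen bonds ----------------------------------------

    # heavy-atom surrogate: the acceptor must not sit behind any covalent
    # bond of the donor carbon (internal constant, not user-tunable)
    _WHB_NEIGHBOR_MIN = 80.0

    def detect_weak_hbonds(self) -> list[AtomicInteraction]:
        cfg = self.config
        out = []
        for a, b, d in self._cross_heavy_pairs(cfg["weak_hbond.ca_max"]):
            for don, acc in ((a, b), (b, a)):
                if don.element != "C" or acc.element not in ("O", "N"):
                    continue
                ann_d = self.ann[don]
                if not self.ann[acc].is_acceptor:
                    continue
                hs = ann_d.attached_hydrogens
                if hs:  # explicit C-H present in the input
                    got = None
                    for h in hs:
                        d_ha = float(np.linalg.norm(h.coords - acc.coords))
                        ang = _angle(don.coords, h.coords, acc.coords)
                        if (d_ha <= cfg["weak_hbond.ha_max"]
                                and ang >= cfg["weak_hbond.cha_min"]):
                            got = ang if got is None else max(got, ang)
                    if got is not None:
                        out.append(self._mk("weak_hbond", don, acc, d, got))
                elif ann_d.is_weak_donor_carbon:
                    nbrs = self._neighbors(don)
                    if all(_angle(n.coords, don.coords, acc.coords)
                           >= self._WHB_NEIGHBOR_MIN for n in nbrs):
                        out.append(self._mk("weak_hbond", don, acc, d))
        return _dedup_pairs(out)

    # -- bridged contacts --------------------------------------------------

    def detect_bridged(self) -> list[AtomicInteraction]:
        cfg = self.config
        out = []
        # water-mediated: O/N partner atoms within reach of the same water O
        wmax = cfg["water_mediated.max"]
        for wat in self.structure.waters():
            w = next((a for a in wat.atoms if a.element == "O"), None)
            if w is None:
                continue
            legs1 = self._polar_within(self.side1, w.coords, wmax)
            legs2 = self._polar_within(self.side2, w.coords, wmax)
            for a1, d1 in legs1:
                for a2, d2 in legs2:
                    out.append(self._mk(
                        "water_mediated", a1, a2, max(d1, d2),
                        mediator=(wat.key, w.name), legs=(d1, d2),
                        covered={("w", id(a1), id(a2), id(w))}))
        # metal-mediated: O/N/S coordinating the same ion
        for ion in self.structure.metal_ions():
            m = ion.atoms[0]
            el = m.element.capitalize() if len(m.element) > 1 else m.element
            mmax = (cfg["metal_mediated.tight"] if el in TIGHT_METALS
                    else cfg["metal_mediated.loose"])
            coord1 = self._coordinating(self.side1, m.coords, mmax)
            coord2 = self._coordinating(self.side2, m.coords, mmax)
            for a1, d1 in coord1:
                for a2, d2 in coord2:
                    out.append(self._mk(
                        "metal_mediated", a1, a2, max(d1, d2),
                        mediator=(ion.key, m.name), legs=(d1, d2),
                        covered={("m", id(a1), id(a2), id(m))}))
        return out

    def _polar_within(self, side: _Side, center: np.ndarray, cutoff: float
                      ) -> list[tuple[Atom, float]]:
        if side.tree is None:
            return []
        out = []
        for i in side.tree.query_ball_point(center, r=cutoff):
            a = side.heavy[i]
            if a.element in ("O", "N"):
                d = float(np.linalg.norm(a.coords - center))
                if d <= cutoff:
                    out.append((a, d))
        return out

    def _coordinating(self, side: _Side, center: np.ndarray, cutoff: float
                      ) -> list[tuple[Atom, float]]:
        if side.tree is None:
            return []
        out = []
        for i in side.tree.query_ball_point(center, r=cutoff):
            a = side.heavy[i]
            if a.element in ("O", "N", "S"):
                d = float(np.linalg.norm(a.coords - center))
                if d <= cutoff:
                    out.append((a, d))
        return out

    # -- disulfide ---------------------------------------------------------

    def detect_disulfide(self) -> list[AtomicInteraction]:
        cfg = self.config
        out = []
        for a, b, d in self._cross_heavy_pairs(cfg["disulfide.max"]):
            if (a.name == "SG" and b.name == "SG"
                    and self._res(a).key.residue_name == "CYS"
                    and self._res(b).key.residue_name == "CYS"):
                # the covalent bond subsumes contacts of the bonded unit
                cov = {_pair_key(*self._oriented(x, y))
                       for x in [a] + self._neighbors(a)
                       for y in [b] + self._neighbors(b)}
                out.append(self._mk("disulfide", a, b, d, covered=cov))
        return out

    # -- halogen bonds -----------------------------------------------------

    def detect_halogen_bonds(self) -> list[AtomicInteraction]:
        cfg = self.config
        out = []
        max_reach = (self.tables.vdw("I") + self.tables.vdw("S")
                     + cfg["halogen.extra"])
        for a, b, d in self._cross_heavy_pairs(max_reach):
            for x, acc in ((a, b), (b, a)):
                if not self.ann[x].is_halogen:
                    continue
                if acc.element not in ("O", "N", "S"):
                    continue
                if d > (self.ann[x].vdw_radius + self.ann[acc].vdw_radius
                        + cfg["halogen.extra"]):
                    continue
                carbons = [c for c in self._neighbors(x) if c.element == "C"]
                for c in carbons:
                    ang = _angle(c.coords, x.coords, acc.coords)
                    if ang >= cfg["halogen.cxa_min"]:
                        out.append(self._mk("halogen_bond", x, acc, d, ang))
                        break
        return _dedup_pairs(out)

    # -- pi family ---------------------------------------------------------

    def _ring_member_ids(self) -> set[int]:
        return {id(a) for rs in self.rings for a in rs.atoms}

    def detect_pi_family(self) -> list[AtomicInteraction]:
        cfg = self.config
        rings1 = [r for r in self.rings if self.ring_side[id(r)] == 1]
        rings2 = [r for r in self.rings if self.ring_side[id(r)] == 2]
        out: list[AtomicInteraction] = []

        # ring-ring (pi-pi): stacked or T-shaped
        best_rr: dict[tuple, AtomicInteraction] = {}
        for r1 in rings1:
            for r2 in rings2:
                d = float(np.linalg.norm(r1.centroid - r2.centroid))
                if d > cfg["pi_pi.max"]:
                    continue
                theta = _plane_angle(r1.normal, r2.normal)
                stacked = theta <= cfg["pi_pi.planar_max"]
                if stacked:
                    delta = r2.centroid - r1.centroid
                    off = float(np.linalg.norm(
                        delta - np.dot(delta, r1.normal) * r1.normal))
                    if off > cfg["pi_pi.offset_max"]:
                        stacked = False
                tshape = cfg["pi_pi.t_min"] <= theta <= 90.0
                if not (stacked or tshape):
                    continue
                cov = {_pair_key(x, y) for x in r1.atoms for y in r2.atoms}
                ia = AtomicInteraction(
                    klass="pi_pi", res1=r1.residue, res2=r2.residue,
                    atom1=_ring_label(r1), atom2=_ring_label(r2),
                    distance=d, angle=theta, covered=frozenset(cov))
                k = (r1.residue, r2.residue)  # fused rings: keep shortest
                if k not in best_rr or d < best_rr[k].distance:
                    best_rr[k] = ia
        out.extend(best_rr.values())

        # atom probes against rings of the other side
        ring_members = self._ring_member_ids()
        best_probe: dict[tuple, tuple[Atom, RingSystem, AtomicInteraction]] = {}
        for rings, probe_side in ((rings1, self.side2), (rings2, self.side1)):
            if not rings or probe_side.tree is None:
                continue
            for rs in rings:
                reach = max(cfg["cation_pi.max"], cfg["amino_pi.max"],
                            cfg["pi_pi.max"])
                idx = probe_side.tree.query_ball_point(rs.centroid, r=reach)
                for i in idx:
                    p = probe_side.heavy[i]
                    if id(p) in ring_members:
                        continue  # ring atoms interact as rings, not probes
                    ia = self._classify_probe(p, rs)
                    if ia is None:
                        continue
                    k = (id(p), rs.residue, ia.klass)
                    if (k not in best_probe
                            or ia.distance < best_probe[k][2].distance):
                        best_probe[k] = (p, rs, ia)
        # one pi contact per functional group and ring: a probe covalently
        # bonded to an already-accepted (stronger or closer) probe on the
        # same ring describes the same physical contact and is dropped
        accepted_probes: dict[int, list[Atom]] = {}
        order = {c: i for i, c in enumerate(_PI_PROBE_ORDER)}
        for p, rs, ia in sorted(best_probe.values(),
                                key=lambda t: (order[t[2].klass],
                                               t[2].distance)):
            taken = accepted_probes.setdefault(id(rs), [])
            if any(np.linalg.norm(p.coords - q.coords) < COVALENT_MAX
                   and self._res(p) is self._res(q) for q in taken):
                continue
            taken.append(p)
            out.append(ia)
        return out

    def _classify_probe(self, p: Atom, rs: RingSystem
                        ) -> AtomicInteraction | None:
        """First matching pi subclass in precedence order for one probe atom
        against one ring."""
        cfg = self.config
        ann = self.ann[p]
        d = float(np.linalg.norm(p.coords - rs.centroid))
        alpha = _axial_angle(rs.normal, rs.centroid, p.coords)
        hs = ann.attached_hydrogens
        cov = {_pair_key(*self._oriented(p, x)) for x in rs.atoms}

        def make(klass, dist, ang):
            a1, a2 = self._oriented(p, rs.atoms[0])
            if a1 is p:
                return AtomicInteraction(klass, self._key(p), rs.residue,
                                         p.name, _ring_label(rs), dist, ang,
                                         covered=frozenset(cov))
            return AtomicInteraction(klass, rs.residue, self._key(p),
                                     _ring_label(rs), p.name, dist, ang,
                                     covered=frozenset(cov))

        if (ann.charge_group == "cationic" and p.element == "N"
                and d <= cfg["cation_pi.max"]
                and alpha <= cfg["cation_pi.axial_max"]):
            return make("cation_pi", d, alpha)
        if (ann.charge_group == "anionic" and p.element == "O"
                and d <= cfg["anion_pi.max"]
                and alpha <= cfg["anion_pi.axial_max"]):
            return make("anion_pi", d, alpha)
        if (p.element in ("O", "N") and ann.charge_group == "neutral"
                and ann.is_acceptor and d <= cfg["lone_pair_pi.max"]
                and alpha <= cfg["lone_pair_pi.axial_max"]
                and not _h_toward(hs, p, rs.centroid)):
            return make("lone_pair_pi", d, alpha)
        if (ann.is_amino_pi and ann.charge_group == "neutral"
                and d <= cfg["amino_pi.max"]
                and alpha <= cfg["amino_pi.axial_max"]):
            return make("amino_pi", d, alpha)
        if ann.is_donor_heavy and p.element in ("O", "N", "S"):
            got = self._h_centroid_hit(p, hs, rs, cfg["onsh_pi.h_max"],
                                       cfg["onsh_pi.heavy_max"],
                                       cfg["onsh_pi.axial_max"])
            if got is not None:
                return make("onsh_pi", got[0], got[1])
        if p.element == "C" and (hs or ann.is_weak_donor_carbon):
            got = self._h_centroid_hit(p, hs, rs, cfg["ch_pi.h_max"],
                                       cfg["ch_pi.heavy_max"],
                                       cfg["ch_pi.axial_max"])
            if got is not None:
                return make("ch_pi", got[0], got[1])
        return None

    def _h_centroid_hit(self, p: Atom, hs: list[Atom], rs: RingSystem,
                        h_max: float, heavy_max: float, axial_max: float
                        ) -> tuple[float, float] | None:
        """(distance, axial angle) via explicit H when present, else the
        heavy-atom surrogate; the stored distance is heavy-atom->centroid."""
        d_heavy = float(np.linalg.norm(p.coords - rs.centroid))
        if hs:
            best = None
            for h in hs:
                dh = float(np.linalg.norm(h.coords - rs.centroid))
                ah = _axial_angle(rs.normal, rs.centroid, h.coords)
                if dh <= h_max and ah <= axial_max:
                    if best is None or dh < best[0]:
                        best = (d_heavy, ah)
            return best
        alpha = _axial_angle(rs.normal, rs.centroid, p.coords)
        if d_heavy <= heavy_max and alpha <= axial_max:
            return (d_heavy, alpha)
        return None

    # -- vdW and clashes ---------------------------------------------------

    def detect_vdw_and_clashes(self, accepted: list[AtomicInteraction]
                               ) -> list[AtomicInteraction]:
        """Emit vdW contacts for unclassified atom pairs and apply the clash
        flag: any pair closer than the vdW-radii sum marks its record (the
        classified one when the pair belongs to one, else its own vdW
        record) with the asterisk semantics."""
        cfg = self.config
        covered: set = set()
        for ia in accepted:
            covered |= set(k for k in ia.covered if isinstance(k, tuple)
                           and len(k) == 2)
        max_reach = 2 * max(self.tables.vdw_radii.values()) + cfg["vdw.tol"]
        out = []
        for a, b, d in self._cross_heavy_pairs(max_reach):
            a1, b1 = self._oriented(a, b)
            key = _pair_key(a1, b1)
            vdw_sum = self.ann[a].vdw_radius + self.ann[b].vdw_radius
            is_clash = d < vdw_sum - cfg["clash.tol"]
            if key in covered:
                if is_clash:
                    for ia in accepted:
                        # disulfides are covalent: never clash-flagged
                        if key in ia.covered and ia.klass != "disulfide":
                            ia.clash = True
                continue
            if d <= vdw_sum + cfg["vdw.tol"]:
                polar = (a.element in ("N", "O") or b.element in ("N", "O"))
                ia = self._mk("vdw_polar" if polar else "vdw_apolar",
                              a, b, d)
                ia.clash = is_clash
                out.append(ia)
        return out

    # -- orchestration -----------------------------------------------------

    def classify(self) -> InterfaceReport:
        contacts = self.residue_contacts()
        contact_keys = {(r1, r2) for r1, r2, _ in contacts}

        candidates: list[AtomicInteraction] = []
        candidates += self.detect_disulfide()
        candidates += self.detect_salt_bridges()
        candidates += self.detect_hbonds()
        candidates += self.detect_halogen_bonds()
        candidates += self.detect_weak_hbonds()
        candidates += self.detect_pi_family()

        accepted = _resolve_precedence(candidates)
        mediated = self.detect_bridged()
        vdw = self.detect_vdw_and_clashes(accepted)

        # keep direct records only between residues inside the interface
        direct = [ia for ia in accepted + vdw
                  if (ia.res1, ia.res2) in contact_keys]
        all_records = direct + mediated

        pair_map: dict[tuple[ResidueKey, ResidueKey], ResiduePairContact] = {}
        min_d = {(r1, r2): d for r1, r2, d in contacts}
        for ia in all_records:
            k = (ia.res1, ia.res2)
            if k not in pair_map:
                pair_map[k] = ResiduePairContact(
                    ia.res1, ia.res2,
                    min_distance=min_d.get(k, self._direct_min_distance(*k)))
            pair_map[k].interactions.append(ia)
        # proximal fallback: in-cutoff pairs with no classified interaction
        for r1, r2, d in contacts:
            if (r1, r2) not in pair_map:
                pa, pb, dmin = self._closest_atoms(r1, r2)
                prox = AtomicInteraction("proximal", r1, r2, pa, pb, dmin)
                pair_map[(r1, r2)] = ResiduePairContact(r1, r2, d, [prox])

        pairs = sorted(pair_map.values(),
                       key=lambda p: (p.res1.chain_id, p.res1.seq_number,
                                      p.res1.insertion_code, p.res2.chain_id,
                                      p.res2.seq_number, p.res2.insertion_code))
        return InterfaceReport(self.selection, self.config, pairs)

    def _direct_min_distance(self, k1: ResidueKey, k2: ResidueKey) -> float:
        r1 = next(r for r in self.side1.residues if r.key == k1)
        r2 = next(r for r in self.side2.residues if r.key == k2)
        return min(float(np.linalg.norm(a.coords - b.coords))
                   for a in r1.heavy_atoms() for b in r2.heavy_atoms())

    def _closest_atoms(self, k1: ResidueKey, k2: ResidueKey
                       ) -> tuple[str, str, float]:
        r1 = next(r for r in self.side1.residues if r.key == k1)
        r2 = next(r for r in self.side2.residues if r.key == k2)
        best = (None, None, math.inf)
        for a in r1.heavy_atoms():
            for b in r2.heavy_atoms():
                d = float(np.linalg.norm(a.coords - b.coords))
                if d < best[2]:
                    best = (a.name, b.name, d)
        return best


def _h_toward(hs: list[Atom], p: Atom, target: np.ndarray,
              tol_deg: float = 50.0) -> bool:
    """True when some attached hydrogen points within tol_deg of p->target
    (the geometry that makes an O/N a donor rather than a lone-pair face)."""
    v = target - p.coords
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        return False
    for h in hs:
        w = h.coords - p.coords
        nw = np.linalg.norm(w)
        if nw < 1e-9:
            continue
        cosv = float(np.dot(v, w) / (nv * nw))
        if math.degrees(math.acos(max(-1.0, min(1.0, cosv)))) <= tol_deg:
            return True
    return False


def _ring_label(rs: RingSystem) -> str:
    return "ring(" + "-".join(rs.ring_atoms) + ")"


def _dedup_pairs(records: list[AtomicInteraction]) -> list[AtomicInteraction]:
    """One record per (res1, atom1, res2, atom2, klass)."""
    seen = {}
    for ia in records:
        k = (ia.klass, ia.res1, ia.atom1, ia.res2, ia.atom2)
        if k not in seen or ia.distance < seen[k].distance:
            seen[k] = ia
    return list(seen.values())


def _resolve_precedence(candidates: list[AtomicInteraction]
                        ) -> list[AtomicInteraction]:
    """Accept candidates strongest-first; a candidate whose covered atom
    pairs intersect an accepted stronger record is dropped."""
    covered: set = set()
    accepted: list[AtomicInteraction] = []
    for ia in sorted(candidates,
                     key=lambda x: (_RANK[x.klass], x.distance)):
        if ia.covered & covered:
            continue
        accepted.append(ia)
        covered |= set(ia.covered)
    return accepted


# ---------------------------------------------------------------------------
# public module-level operations

def residue_contacts(structure: Structure, selection: PartnerSelection,
                     config: GeometryConfig | None = None
                     ) -> list[tuple[ResidueKey, ResidueKey, float]]:
    return InteractionEngine(structure, selection, config).residue_contacts()


def classify_interface(structure: Structure, selection: PartnerSelection,
                       config: GeometryConfig | None = None,
                       tables: ChemTables | None = None,
                       compute_sasa: bool = True,
                       input_label: str = "") -> InterfaceReport:
    """Full interface analysis: annotate, place hydrogens (per hydrogen
    mode), enumerate contacts, run all detectors with precedence, apply
    vdW/clash and proximal rules, and attach per-residue buried surface
    areas."""
    t0 = time.time()
    engine = InteractionEngine(structure, selection, config, tables)
    report = engine.classify()
    if compute_sasa:
        from .sasa import buried_surface
        cfg = engine.config
        report.sasa = buried_surface(
            engine.structure, engine.selection,
            probe=cfg["sasa.probe"], n_points=cfg.switches["sasa_points"],
            include_waters=cfg.switches["include_waters_in_sasa"],
            bsa_min=cfg["sasa.bsa_min"], tables=engine.tables)
    n_atoms = sum(1 for _ in structure.atoms())
    report.provenance = {
        "tool": "intermaps",
        "input": input_label or structure.entry_id,
        "n_atoms": n_atoms,
        "empty_interface": not report.pairs,
        "config": engine.config.to_dict(),
        "elapsed_s": round(time.time() - t0, 3),
    }
    return report
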