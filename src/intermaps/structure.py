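"""Uniform structure hierarchy and partner selection.

Parses PDB/mmCIF files (via gemmi) into a light-weight chain -> residue ->
atom hierarchy with a single model and a single conformer per atom, and
resolves the two-partner selection that all downstream interface analysis
operates on.
"""
from __future__ import annotations

import io
import logging
import math
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

import gemmi

log = logging.getLogger(__name__)

__all__ = [
    "Atom", "ResidueKey", "Residue", "Structure", "PartnerSelection",
    "ParseError", "SelectionError",
    "parse_structure", "select_partners", "neighbor_atom_pairs", "write_pdb",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}
METAL_ELEMENTS = {"NA", "K", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD"}

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
RNA_NAMES = {"A", "C", "G", "U", "I"}
DNA_NAMES = {"DA", "DC", "DG", "DT", "DU", "DI"}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as a structure."""


class SelectionError(ValueError):
    """Raised for invalid partner selections (unknown chain, overlap, ...)."""


@dataclass(eq=False)
class Atom:
    """A single atom; hashable by identity so annotation maps can key on it."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Atom({self.name} #{self.serial} {self.element})"

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue within one model."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __str__(self) -> str:
        ic = self.insertion_code or ""
        return f"{self.chain_id}:{self.seq_number}{ic}:{self.residue_name}"


@dataclass
class Residue:
    key: ResidueKey
    category: str  # protein | dna | rna | water | metal-ion | other-ligand
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_polymer(self) -> bool:
        return self.category in ("protein", "dna", "rna")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    entry_id: str
    chains: list[tuple[str, list[Residue]]]
    source_format: str = "pdb"

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(chain_id)

    def residues(self) -> Iterable[Residue]:
        for _, residues in self.chains:
            yield from residues

    def atoms(self) -> Iterable[Atom]:
        for res in self.residues():
            yield from res.atoms

    def find_residue(self, key: ResidueKey) -> Residue | None:
        for res in self.residues():
            if (res.key.chain_id, res.key.seq_number, res.key.insertion_code) == (
                key.chain_id, key.seq_number, key.insertion_code,
            ):
                return res
        return None

    def polymer_chain_ids(self) -> list[str]:
        return [cid for cid, residues in self.chains
                if any(r.is_polymer for r in residues)]

    def waters(self) -> list[Residue]:
        return [r for r in self.residues() if r.category == "water"]

    def metal_ions(self) -> list[Residue]:
        return [r for r in self.residues() if r.category == "metal-ion"]


@dataclass
class PartnerSelection:
    """The two molecule groups whose mutual interface is analyzed.

    Waters and metal ions are never part of a partner: they act as mediators
    only. ``residues1``/``residues2`` hold the resolved residue objects in
    file order.
    """

    partner1: list[tuple[str, tuple[int, int] | None]]
    partner2: list[tuple[str, tuple[int, int] | None]]
    residues1: list[Residue]
    residues2: list[Residue]
    labels: tuple[str, str] = ("partner1", "partner2")

    def keys1(self) -> set[ResidueKey]:
        return {r.key for r in self.residues1}

    def keys2(self) -> set[ResidueKey]:
        return {r.key for r in self.residues2}

    def side_of(self, key: ResidueKey) -> int:
        """1, 2 or 0 (neither partner)."""
        ident = (key.chain_id, key.seq_number, key.insertion_code)
        for r in self.residues1:
            if (r.key.chain_id, r.key.seq_number, r.key.insertion_code) == ident:
                return 1
        for r in self.residues2:
            if (r.key.chain_id, r.key.seq_number, r.key.insertion_code) == ident:
                return 2
        return 0


# ---------------------------------------------------------------------------
# parsing

_ELEMENT_GUESS = re.compile(r"[A-Za-z]")

TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "NI", "CO", "CD", "SE",
    "CA",  # calcium only in single-atom het groups; handled below
}


def infer_element(atom_name: str, residue_name: str, is_hetero: bool) -> str:
    """Best-effort element from a PDB atom name when the element column is absent.

    Disambiguates the classic 'CA' case: alpha carbon in polymers, calcium in
    single-atom het groups named CA.
    """
    name = atom_name.strip()
    if not name:
        return ""
    # leading digits (e.g. 1HB, 2HO') mark hydrogens in old files
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "HDQ" and (name[0].isdigit() or stripped[0] == "H"):
        return "H"
    upper = stripped.upper()
    if is_hetero and upper in TWO_LETTER_ELEMENTS and upper == residue_name.strip().upper():
        return upper.capitalize() if len(upper) > 1 else upper
    if upper[:2] in TWO_LETTER_ELEMENTS and is_hetero and residue_name.strip().upper() not in AMINO3:
        two = upper[:2]
        return two[0] + two[1].lower()
    return upper[0]


def _categorize(resname: str, atoms: list[Atom], is_het: bool) -> str:
    name = resname.strip().upper()
    if name in WATER_NAMES:
        return "water"
    heavy = [a for a in atoms if a.element != "H"]
    if len(heavy) == 1 and heavy[0].element.upper() in METAL_ELEMENTS:
        return "metal-ion"
    if name in AMINO3:
        return "protein"
    if name in RNA_NAMES:
        return "rna"
    if name in DNA_NAMES:
        return "dna"
    atom_names = {a.name for a in atoms}
    if {"N", "CA", "C"} <= atom_names:
        return "protein"
    if "C1'" in atom_names or "C1*" in atom_names:
        return "rna" if ("O2'" in atom_names or "O2*" in atom_names) else "dna"
    return "other-ligand"


def _resolve_altlocs(raw_atoms: list[Atom], key: ResidueKey) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to altloc 'A'
    (or the first encountered)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            chosen = group[0]
        else:
            chosen = max(group, key=lambda a: (a.occupancy, a.altloc == "A",
                                               -ord(a.altloc or "z")))
            log.debug("altloc resolution at %s %s: kept '%s'", key, name,
                      chosen.altloc)
        chosen.altloc = ""
        out.append(chosen)
    return out


def _detect_format(text: str) -> str:
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("data_"):
            return "mmcif"
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "TITLE",
                   "CRYST1", "COMPND", "SEQRES", "EXPDTA", "TER", "ANISOU"):
            return "pdb"
        if s.startswith(("loop_", "_")):
            return "mmcif"
    raise ParseError(f"cannot detect structure format (first token: "
                     f"{text.strip().splitlines()[0][:40] if text.strip() else '<empty>'!r})")


def parse_structure(source, format_hint: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    source
        A filesystem path, a text string holding file content, or a readable
        text stream.
    format_hint
        ``pdb``, ``mmcif`` or ``auto``.  Auto-detection: mmCIF content begins
        with ``data_``; PDB has fixed-width record names.

    Only the first model is kept (a warning is logged for multi-model files);
    alternate conformers are collapsed to the highest-occupancy one.
    """
    if isinstance(source, (str, os.PathLike)) and (
            isinstance(source, os.PathLike) or (len(str(source)) < 4096
            and "\n" not in str(source) and os.path.exists(source))):
        with open(source, "r", errors="replace") as fh:
            text = fh.read()
        name_hint = os.path.basename(str(source))
    elif isinstance(source, str):
        text = source
        name_hint = ""
    elif isinstance(source, (io.IOBase, io.TextIOBase)) or hasattr(source, "read"):
        raw = source.read()
        text = raw.decode(errors="replace") if isinstance(raw, bytes) else raw
        name_hint = getattr(source, "name", "")
    else:
        raise TypeError(f"unsupported source type: {type(source)!r}")

    if not text.strip():
        raise ParseError("empty input")

    fmt = format_hint if format_hint in ("pdb", "mmcif") else _detect_format(text)

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{fmt} parse failure: {exc}") from exc

    if len(st) == 0:
        raise ParseError("no coordinate model found")
    if len(st) > 1:
        log.warning("multi-model file: keeping model 1 of %d", len(st))
    model = st[0]

    st.setup_entities()

    chains: list[tuple[str, list[Residue]]] = []
    serial = 0
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            raw_atoms: list[Atom] = []
            res_is_het = res.het_flag == "H"
            for at in res:
                serial += 1
                el = at.element.name if at.element and at.element.name != "X" else ""
                if not el:
                    el = infer_element(at.name, res.name, res_is_het)
                if el == "D":
                    el = "H"
                coords = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
                if not np.all(np.isfinite(coords)):
                    raise ParseError(f"non-finite coordinates at atom {at.name} "
                                     f"of {ch.name}/{res.seqid.num}")
                raw_atoms.append(Atom(
                    serial=serial, name=at.name, element=el, coords=coords,
                    altloc=(at.altloc or ""), occupancy=at.occ,
                    is_hetero=res_is_het,
                ))
            icode = res.seqid.icode.strip()
            key = ResidueKey(ch.name, res.seqid.num, icode, res.name.strip())
            atoms = _resolve_altlocs(raw_atoms, key)
            is_het = any(a.is_hetero for a in atoms)
            residues.append(Residue(key, _categorize(res.name, atoms, is_het), atoms))
        if residues:
            chains.append((ch.name, residues))

    structure = Structure(entry_id=(st.name or name_hint or "UNKNOWN"),
                          chains=chains, source_format=fmt)
    if not structure.polymer_chain_ids():
        raise ParseError("no polymer chains in input")
    return structure


# ---------------------------------------------------------------------------
# partner selection

_RANGE_RE = re.compile(r"^\s*([^:,\s]+)\s*(?::\s*(-?\d+)\s*-\s*(-?\d+)\s*)?$")


def parse_selection_expr(expr) -> list[tuple[str, tuple[int, int] | None]]:
    """Parse a selection mini-language string: ``"A"``, ``"A:34-36"``,
    ``"B:403-461,C"``. Structured input (list of (chain, range) tuples)
    passes through."""
    if isinstance(expr, (list, tuple)) and not isinstance(expr, str):
        out = []
        for item in expr:
            if isinstance(item, str):
                out.extend(parse_selection_expr(item))
            else:
                cid, rng = item
                out.append((str(cid), tuple(rng) if rng is not None else None))
        return out
    out = []
    for part in str(expr).split(","):
        if not part.strip():
            continue
        m = _RANGE_RE.match(part)
        if not m:
            raise SelectionError(f"cannot parse selection token {part.strip()!r} "
                                 f"(expected 'A' or 'A:34-36')")
        cid, lo, hi = m.group(1), m.group(2), m.group(3)
        out.append((cid, (int(lo), int(hi)) if lo is not None else None))
    if not out:
        raise SelectionError("empty selection expression")
    return out


def _resolve(structure: Structure,
             items: list[tuple[str, tuple[int, int] | None]]) -> list[Residue]:
    resolved: list[Residue] = []
    seen: set[tuple[str, int, str]] = set()
    for cid, rng in items:
        try:
            chain_residues = structure.chain(cid)
        except KeyError:
            raise SelectionError(
                f"unknown chain {cid!r}; available chains: "
                f"{', '.join(structure.chain_ids())}") from None
        picked = []
        for res in chain_residues:
            if res.category in ("water", "metal-ion"):
                continue  # mediators, never partners
            if rng is not None and not (rng[0] <= res.key.seq_number <= rng[1]):
                continue
            picked.append(res)
        if rng is not None and not picked:
            raise SelectionError(
                f"range {rng[0]}-{rng[1]} selects no residue in chain {cid!r}")
        if rng is None and not picked:
            raise SelectionError(f"chain {cid!r} has no selectable residues")
        for res in picked:
            ident = (res.key.chain_id, res.key.seq_number, res.key.insertion_code)
            if ident not in seen:
                seen.add(ident)
                resolved.append(res)
    return resolved


def select_partners(structure: Structure, spec1, spec2,
                    labels: tuple[str, str] = ("partner1", "partner2"),
                    ) -> PartnerSelection:
    """Validate and resolve the two partner selections.

    Raises :class:`SelectionError` when a chain is unknown, a range is empty,
    or the partners share a residue.
    """
    items1 = parse_selection_expr(spec1)
    items2 = parse_selection_expr(spec2)
    res1 = _resolve(structure, items1)
    res2 = _resolve(structure, items2)
    ids1 = {(r.key.chain_id, r.key.seq_number, r.key.insertion_code) for r in res1}
    ids2 = {(r.key.chain_id, r.key.seq_number, r.key.insertion_code) for r in res2}
    shared = ids1 & ids2
    if shared:
        ex = sorted(shared)[0]
        raise SelectionError(
            f"partners overlap: {len(shared)} shared residue(s), e.g. chain "
            f"{ex[0]} residue {ex[1]}{ex[2]}")
    return PartnerSelection(items1, items2, res1, res2, labels)


# ---------------------------------------------------------------------------
# neighbor search

def neighbor_atom_pairs(atoms1: Sequence[Atom], atoms2: Sequence[Atom],
                        cutoff: float) -> list[tuple[Atom, Atom, float]]:
    """All inter-partner atom pairs with Euclidean distance <= cutoff.

    Uses a KD-tree, so cost scales near-linearly with atom count for
    biological densities; each qualifying pair is reported exactly once as
    (atom_from_first_list, atom_from_second_list, distance).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not atoms1 or not atoms2:
        return []
    c1 = np.array([a.coords for a in atoms1])
    c2 = np.array([a.coords for a in atoms2])
    tree1 = cKDTree(c1)
    tree2 = cKDTree(c2)
    pairs = tree1.query_ball_tree(tree2, r=cutoff)
    out: list[tuple[Atom, Atom, float]] = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(c1[i] - c2[j]))
            if d <= cutoff:
                out.append((atoms1[i], atoms2[j], d))
    return out


# ---------------------------------------------------------------------------
# fixture writer (PDB)

def write_pdb(structure: Structure) -> str:
    """Serialize the hierarchy to PDB text (fixed-width ATOM/HETATM/TER).

    Fixture writer used by the synthetic-motif generator and the round-trip
    tests; not a general-purpose deposition writer.
    """
    lines = []
    serial = 0
    for cid, residues in structure.chains:
        last_polymer = None
        for res in residues:
            rec = "HETATM" if (not res.is_polymer) else "ATOM"
            for a in res.atoms:
                serial += 1
                name = a.name
                # PDB alignment rule: 1-letter element names start in col 14
                if len(name) < 4 and (len(a.element) == 1 or not a.element):
                    name = " " + name
                icode = res.key.insertion_code or " "
                el = (a.element or "").rjust(2)[:2]
                lines.append(
                    f"{rec:<6}{serial:>5} {name:<4}{'':1}{res.key.residue_name:<3}"
                    f" {cid[:1]:1}{res.key.seq_number:>4}{icode:1}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {el:>2}")
            last_polymer = res if res.is_polymer else last_polymer
        if last_polymer is not None:
            serial += 1
            lines.append(f"TER   {serial:>5}      {last_polymer.key.residue_name:<3} "
                         f"{cid[:1]:1}{last_polymer.key.seq_number:>4}")
    lines.append("END")
    return "\n".join(lines) + "\n"
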