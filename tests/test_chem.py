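"""Atom annotation, ring detection and polar-hydrogen placement."""
import math

import numpy as np
import pytest

from intermaps import (annotate, find_rings, parse_structure,
                       place_polar_hydrogens, write_pdb)
from intermaps.chem import ChemTables
from intermaps.fixtures import MotifSpec, make_motif
from intermaps.structure import Atom, Residue, ResidueKey, Structure
from intermaps.templates import TEMPLATES

from conftest import random_rotation

# independent hand-built atom inventory for the 20 amino acids: heavy atoms
# and, among them, the polar (N/O) ones
SIDECHAINS = {
    "ALA": ["CB"], "GLY": [],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"], "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"], "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"], "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"], "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"], "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
            "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}
POLAR_SIDECHAIN = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"OD1", "ND2"},
    "ASP": {"OD1", "OD2"}, "GLN": {"OE1", "NE2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"},
}


def synthetic_peptide() -> Structure:
    """All 20 residues, atoms spread far apart (annotation is geometry-free
    except for attached-H detection, which this structure does not use)."""
    residues = []
    serial = 0
    rng = np.random.default_rng(2024)  # non-collinear but deterministic
    for i, (resname, side) in enumerate(sorted(SIDECHAINS.items()), 1):
        atoms = []
        for j, name in enumerate(["N", "CA", "C", "O"] + side):
            serial += 1
            jitter = rng.uniform(-0.8, 0.8, 3)
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              coords=np.array([10.0 * i, 3.0 * j, 0.0])
                              + jitter))
        residues.append(Residue(ResidueKey("A", i, "", resname), "protein",
                                atoms))
    return Structure("PEP20", [("A", residues)], "pdb")


def template_structure(resname, chain="A", num=1, category=None):
    atoms = []
    for j, (name, xyz) in enumerate(TEMPLATES[resname].items(), 1):
        el = {"CL": "Cl", "MG": "Mg"}.get(name, name.lstrip("0123456789")[0])
        atoms.append(Atom(serial=j, name=name, element=el,
                          coords=np.array(xyz)))
    if category is None:
        category = "rna" if resname == "G" else "protein"
    res = Residue(ResidueKey(chain, num, "", resname), category, atoms)
    return Structure("T", [(chain, [res])], "pdb")


class TestAnnotate:
    def test_polarity_matches_hand_built_table_for_all_20_residues(self):
        st = synthetic_peptide()
        ann = annotate(st)
        for res in st.residues():
            polar = {"N", "O"} | POLAR_SIDECHAIN.get(res.key.residue_name,
                                                     set())
            for a in res.atoms:
                info = ann[a]
                assert info.vdw_radius > 0
                expected = "polar" if a.name in polar else "apolar"
                assert info.polarity == expected, (res.key, a.name)

    def test_asp_carboxylate_oxygen_roles(self):
        st = synthetic_peptide()
        ann = annotate(st)
        asp = next(r for r in st.residues() if r.key.residue_name == "ASP")
        od1 = ann[asp.atom("OD1")]
        assert od1.is_acceptor and od1.charge_group == "anionic"
        assert od1.polarity == "polar" and not od1.is_donor_heavy

    def test_guanine_exocyclic_amine_is_donor_and_amino_pi_capable(self):
        st = template_structure("G")
        ann = annotate(st)
        n2 = ann[list(st.residues())[0].atom("N2")]
        assert n2.is_donor_heavy and n2.is_amino_pi

    def test_unknown_residue_gets_element_fallback(self):
        atoms = [Atom(1, "X1", "N", np.array([0.0, 0, 0])),
                 Atom(2, "X2", "C", np.array([1.5, 0, 0]))]
        res = Residue(ResidueKey("A", 1, "", "XYZ"), "other-ligand", atoms)
        protein = synthetic_peptide()
        st = Structure("U", protein.chains + [("L", [res])], "pdb")
        ann = annotate(st)
        assert ann[atoms[0]].polarity == "polar"
        assert ann[atoms[1]].polarity == "apolar"
        assert ann[atoms[0]].unknown_residue


class TestRings:
    def test_phe_yields_one_planar_six_ring(self):
        st = template_structure("PHE")
        rings = find_rings(st)
        assert len(rings) == 1
        ring = rings[0]
        assert ring.ring_kind == "aromatic-6"
        assert np.linalg.norm(ring.normal) == pytest.approx(1.0)
        coords = np.array([a.coords for a in ring.atoms])
        assert np.allclose(ring.centroid, coords.mean(axis=0))

    def test_guanine_yields_five_and_six_ring(self):
        st = template_structure("G")
        kinds = sorted(r.ring_kind for r in find_rings(st))
        assert kinds == ["aromatic-5", "aromatic-6"]

    def test_ring_frame_is_rotation_equivariant(self):
        st = template_structure("PHE")
        base = find_rings(st)[0]
        rng = np.random.default_rng(5)
        R = random_rotation(rng)
        for res in st.residues():
            for a in res.atoms:
                a.coords = R @ a.coords
        rotated = find_rings(st)[0]
        assert np.allclose(rotated.centroid, R @ base.centroid, atol=1e-9)
        dot = abs(float(np.dot(rotated.normal, R @ base.normal)))
        assert dot == pytest.approx(1.0, abs=1e-9)

    def test_ring_with_missing_atom_is_skipped(self):
        st = template_structure("PHE")
        res = list(st.residues())[0]
        res.atoms = [a for a in res.atoms if a.name != "CZ"]
        assert find_rings(st) == []


class TestHydrogenPlacement:
    def _dipeptide(self):
        """Two template alanines linked by a plausible peptide bond."""
        t = {n: np.array(x) for n, x in TEMPLATES["ALA"].items()}
        c, o, ca = t["C"], t["O"], t["CA"]
        direction = (c - ca) / np.linalg.norm(c - ca)
        shift = c + 1.33 * direction - t["N"]
        atoms1 = [Atom(i + 1, n, n[0], t[n].copy())
                  for i, n in enumerate(["N", "CA", "CB", "C", "O"])]
        atoms2 = [Atom(i + 6, n, n[0], t[n] + shift)
                  for i, n in enumerate(["N", "CA", "CB", "C", "O"])]
        return Structure("DIP", [("A", [
            Residue(ResidueKey("A", 1, "", "ALA"), "protein", atoms1),
            Residue(ResidueKey("A", 2, "", "ALA"), "protein", atoms2),
        ])], "pdb")

    def test_backbone_amide_h_geometry(self):
        st = place_polar_hydrogens(self._dipeptide())
        res2 = list(st.residues())[1]
        h = res2.atom("H")
        assert h is not None
        n = res2.atom("N")
        assert np.linalg.norm(h.coords - n.coords) == pytest.approx(1.01,
                                                                    abs=1e-6)
        # H lies in the C(prev)-N-CA plane, anti to the bisector
        res1 = list(st.residues())[0]
        c_prev, ca = res1.atom("C"), res2.atom("CA")
        normal = np.cross(c_prev.coords - n.coords, ca.coords - n.coords)
        normal /= np.linalg.norm(normal)
        assert abs(float(np.dot(h.coords - n.coords, normal))) < 1e-6

    def test_hydroxyl_aims_at_nearby_acceptor(self):
        pdb_text, _ = make_motif(MotifSpec("hbond"), seed=0)
        # drop the fixture's explicit H so the placement code must act
        text = "\n".join(l for l in pdb_text.splitlines()
                         if " HG " not in l) + "\n"
        st = place_polar_hydrogens(parse_structure(text))
        ser = next(r for r in st.residues()
                   if r.key.residue_name == "SER")
        ala = next(r for r in st.residues()
                   if r.key.residue_name == "ALA")
        og, hg, acc = ser.atom("OG"), ser.atom("HG"), ala.atom("O")
        assert hg is not None
        v1 = og.coords - hg.coords
        v2 = acc.coords - hg.coords
        cosv = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
        angle = math.degrees(math.acos(cosv))
        assert angle >= 120.0

    def test_structures_with_hydrogens_are_left_unchanged(self):
        pdb_text, _ = make_motif(MotifSpec("hbond"), seed=0)
        st = parse_structure(pdb_text)  # SER already carries HG
        ser_before = next(r for r in st.residues()
                          if r.key.residue_name == "SER")
        n_before = len(ser_before.atoms)
        placed = place_polar_hydrogens(st)
        ser_after = next(r for r in placed.residues()
                         if r.key.residue_name == "SER")
        assert len(ser_after.atoms) == n_before

    def test_placement_only_appends_never_moves(self):
        st = self._dipeptide()
        before = {a.serial: a.coords.copy() for a in st.atoms()}
        placed = place_polar_hydrogens(st)
        for a in placed.atoms():
            if a.serial in before:
                assert np.array_equal(a.coords, before[a.serial])
        assert sum(1 for _ in placed.atoms()) > len(before)

    def test_every_donor_has_hydrogen_after_placement(self):
        st = synthetic_peptide()
        # spread-out residues: every donor should still receive its H from
        # local geometry where parents exist
        placed = place_polar_hydrogens(st)
        ann = annotate(placed)
        missing = []
        for res in placed.residues():
            if res.key.residue_name == "PRO":
                continue
            for a in res.atoms:
                if ann[a].is_donor_heavy and not ann[a].attached_hydrogens:
                    missing.append((res.key.residue_name, a.name))
        assert missing == []


def test_chem_tables_roundtrip(tmp_path):
    tables = ChemTables.default()
    assert tables.vdw("C") == pytest.approx(1.70)
    assert tables.vdw("Zz") == tables.vdw_radii["default"]
    # user-editable copy loads identically
    import yaml
    from importlib import resources
    text = resources.files("intermaps.data").joinpath(
        "chem_tables.yaml").read_text()
    p = tmp_path / "chem.yaml"
    p.write_text(text)
    again = ChemTables.from_file(p)
    assert again.vdw_radii == tables.vdw_radii
    assert again.donors == tables.donors
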