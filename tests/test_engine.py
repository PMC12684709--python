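"""Interaction detection, classification, precedence, clash and proximal
rules."""
import math

import numpy as np
import pytest

from intermaps import (GeometryConfig, InteractionEngine, classify_interface,
                       parse_structure, select_partners)
from intermaps.config import ConfigError
from intermaps.engine import DIRECTIONAL_CLASSES
from intermaps.fixtures import (MotifSpec, make_mini_complex, make_motif,
                                report_signature)
from intermaps.structure import Atom, Residue, ResidueKey, Structure
from intermaps.templates import TEMPLATES

from conftest import random_rotation


def tmpl(resname, offset, only=None, rename=None, chain="A", num=1,
         extra=None, category="protein", serial0=0):
    """One template residue shifted by ``offset`` (exact float arithmetic so
    boundary distances are bitwise what the test states)."""
    atoms = []
    serial = serial0
    for name, xyz in TEMPLATES[resname].items():
        if only is not None and name not in only:
            continue
        serial += 1
        el = {"CL": "Cl", "MG": "Mg"}.get(name, name.lstrip("0123456789")[0])
        atoms.append(Atom(serial, name, el, np.array(xyz) + np.array(offset)))
    for name, el, pos in (extra or []):
        serial += 1
        atoms.append(Atom(serial, name, el, np.array(pos, dtype=float)))
    return Residue(ResidueKey(chain, num, "", resname), category, atoms)


def structure_of(*residues):
    chains = {}
    for r in residues:
        chains.setdefault(r.key.chain_id, []).append(r)
    return Structure("T", list(chains.items()), "pdb")


def classify(st, config=None, p1="A", p2="B"):
    sel = select_partners(st, p1, p2)
    return classify_interface(st, sel, config, compute_sasa=False)


def classes_of(report):
    return sorted(ia.klass for ia in report.interactions())


class TestHBond:
    def _donor_acceptor(self, d_no, dha_deg):
        """Ser OG-HG donor against a bare backbone O acceptor with the
        requested N(O)...O distance and D-H...A angle."""
        og = np.array([0.0, 0.0, 0.0])
        acc = np.array([0.0, 0.0, d_no])
        # H at 0.96 from OG such that angle OG-H-acc equals dha_deg
        theta = math.radians(180.0 - dha_deg)
        h = np.array([0.96 * math.sin(theta), 0.0, 0.96 * math.cos(theta)])
        ser = tmpl("SER", (0, 0, 0), only=["OG"],
                   extra=[("HG", "H", h)], chain="A")
        # shift template so OG is at origin
        og_t = np.array(TEMPLATES["SER"]["OG"])
        for a in ser.atoms:
            if a.name == "OG":
                a.coords = og
        ala = tmpl("ALA", (0, 0, 0), only=["O", "C"], chain="B")
        c_dir = np.array(TEMPLATES["ALA"]["C"]) - np.array(TEMPLATES["ALA"]["O"])
        c_dir /= np.linalg.norm(c_dir)
        for a in ala.atoms:
            a.coords = acc if a.name == "O" else acc + 1.23 * np.array([0, 0.3, 0.95])
        return structure_of(ser, ala)

    def test_ideal_geometry_gives_one_hbond(self):
        st = self._donor_acceptor(2.9, 165.0)
        report = classify(st)
        assert classes_of(report).count("hbond") == 1

    def test_angle_below_gate_gives_none(self):
        st = self._donor_acceptor(2.9, 100.0)
        report = classify(st)
        assert "hbond" not in classes_of(report)

    def test_distance_gate(self):
        st = self._donor_acceptor(3.8, 165.0)
        report = classify(st)
        assert "hbond" not in classes_of(report)

    def test_heavy_atom_mode_uses_antecedent_surrogate(self):
        pdb_text, _ = make_motif(MotifSpec("hbond"), seed=0)
        st = parse_structure(pdb_text)
        cfg = GeometryConfig.from_overrides({"hydrogen_mode": "heavy_atom"})
        report = classify(st, cfg)
        assert "hbond" in classes_of(report)


class TestSaltBridge:
    def test_contact_distance_gate(self, classify_motif):
        report, _, _ = classify_motif("salt_bridge", distance=3.2)
        assert classes_of(report) == ["salt_bridge"]
        report, _, _ = classify_motif("salt_bridge", distance=4.5)
        assert "salt_bridge" not in classes_of(report)

    def test_group_level_counting_is_single_record(self, classify_motif):
        # both carboxylate oxygens near NZ must yield one salt bridge
        report, _, _ = classify_motif("salt_bridge", distance=3.5)
        assert classes_of(report).count("salt_bridge") == 1

    def test_subsumes_hbond_label(self, classify_motif):
        """An ionic pair with H-bond geometry is reported as salt_bridge,
        not double-counted as hbond."""
        report, _, _ = classify_motif("salt_bridge", distance=3.0)
        ks = classes_of(report)
        assert "salt_bridge" in ks and "hbond" not in ks


class TestWeakHBond:
    def test_distance_gate(self, classify_motif):
        report, _, _ = classify_motif("weak_hbond", distance=3.3)
        assert "weak_hbond" in classes_of(report)
        report, _, _ = classify_motif("weak_hbond", distance=4.2)
        assert "weak_hbond" not in classes_of(report)


class TestBridged:
    def test_water_mediator_identity(self, classify_motif):
        report, gt, _ = classify_motif("water_mediated")
        recs = [ia for ia in report.interactions()
                if ia.klass == "water_mediated"]
        assert len(recs) == 1
        assert recs[0].mediator[1] == "O"
        assert recs[0].mediator_legs is not None
        assert recs[0].distance == pytest.approx(max(recs[0].mediator_legs))

    def test_metal_coordination_cutoff(self, classify_motif):
        report, _, _ = classify_motif("metal_mediated")
        recs = [ia for ia in report.interactions()
                if ia.klass == "metal_mediated"]
        assert len(recs) == 1 and recs[0].mediator[1] == "MG"
        # stretch the legs beyond the tight-metal cutoff
        report, _, _ = classify_motif("metal_mediated", distance=3.4)
        assert "metal_mediated" not in classes_of(report)


class TestDisulfide:
    def test_canonical_bond_detected_without_clash_flag(self, classify_motif):
        report, _, _ = classify_motif("disulfide")
        recs = [ia for ia in report.interactions() if ia.klass == "disulfide"]
        assert len(recs) == 1 and not recs[0].clash

    def test_distance_gate(self, classify_motif):
        report, _, _ = classify_motif("disulfide", distance=3.5)
        assert "disulfide" not in classes_of(report)

    def test_intra_partner_pair_excluded(self):
        cys1 = tmpl("CYS", (0, 0, 0), chain="A", num=1)
        cys2 = tmpl("CYS", (0, 0, 2.05), chain="A", num=2)
        far = tmpl("ALA", (50, 0, 0), chain="B", num=1)
        report = classify(structure_of(cys1, cys2, far))
        assert "disulfide" not in classes_of(report)


class TestHalogen:
    def test_sigma_hole_angle_gate(self, classify_motif):
        report, _, _ = classify_motif("halogen_bond")
        assert "halogen_bond" in classes_of(report)
        # acceptor at 120 degrees off the C-X axis: rejected
        clb = tmpl("CLB", (0, 0, 0), chain="A", category="other-ligand")
        cl = next(a for a in clb.atoms if a.name == "CL")
        c1 = next(a for a in clb.atoms if a.name == "C1")
        axis = (cl.coords - c1.coords) / np.linalg.norm(cl.coords - c1.coords)
        perp = np.array([0.0, 0.0, 1.0])
        theta = math.radians(180 - 120)
        pos = cl.coords + 3.2 * (math.cos(theta) * axis + math.sin(theta) * perp)
        ala = tmpl("ALA", (0, 0, 0), only=["O"], chain="B")
        ala.atoms[0].coords = pos
        report = classify(structure_of(clb, ala))
        assert "halogen_bond" not in classes_of(report)

    def test_protein_only_complex_has_no_halogen_bonds(self, mini_complex_16):
        report, _, st = mini_complex_16
        engine_classes = {ia.klass for ia in report.interactions()}
        # the only halogen bond must come from the planted CLB motif
        halogen_recs = [ia for ia in report.interactions()
                        if ia.klass == "halogen_bond"]
        assert all(ia.res1.residue_name == "CLB" for ia in halogen_recs)


class TestPiFamily:
    def test_stacked_rings_are_pi_pi(self, classify_motif):
        report, _, _ = classify_motif("pi_pi")
        recs = [ia for ia in report.interactions() if ia.klass == "pi_pi"]
        assert len(recs) == 1
        assert recs[0].angle is not None and recs[0].angle <= 30.0

    def test_cation_pi_wins_over_weaker_subclasses(self, classify_motif):
        report, _, _ = classify_motif("cation_pi")
        pi_records = [ia for ia in report.interactions()
                      if ia.klass.endswith("_pi") or ia.klass == "pi_pi"]
        assert [ia.klass for ia in pi_records] == ["cation_pi"]

    def test_amino_pi_precedence_over_onsh(self, classify_motif):
        """The amide N passes both the amino-pi and (via its H) the onsh-pi
        predicates; precedence keeps amino-pi. Shrinking the amino-pi
        threshold below the geometry exposes the onsh-pi match."""
        report, _, _ = classify_motif("amino_pi")
        assert "amino_pi" in classes_of(report)
        assert "onsh_pi" not in classes_of(report)
        cfg = GeometryConfig.from_overrides({"amino_pi.max": 3.0})
        report, _, _ = classify_motif("amino_pi", config=cfg)
        assert "amino_pi" not in classes_of(report)
        assert "onsh_pi" in classes_of(report)

    def test_lone_pair_requires_non_donor_orientation(self, classify_motif):
        report, _, _ = classify_motif("lone_pair_pi")
        assert "lone_pair_pi" in classes_of(report)
        # the same oxygen with its H aimed at the ring is an O-H...pi donor
        report, _, _ = classify_motif("onsh_pi")
        assert "lone_pair_pi" not in classes_of(report)
        assert "onsh_pi" in classes_of(report)


class TestVdwAndClash:
    def test_apolar_boundary_inside(self):
        a = tmpl("ALA", (0, 0, 0), only=["CB"], chain="A")
        b = tmpl("ALA", (0, 0, 3.9), only=["CB"], chain="B")
        report = classify(structure_of(a, b))
        assert classes_of(report) == ["vdw_apolar"]

    def test_beyond_vdw_is_proximal_only(self):
        a = tmpl("ALA", (0, 0, 0), only=["CB"], chain="A")
        b = tmpl("ALA", (0, 0, 4.2), only=["CB"], chain="B")
        report = classify(structure_of(a, b))
        assert classes_of(report) == ["proximal"]

    def test_clashing_hbond_is_flagged_not_duplicated(self, classify_motif):
        report, _, _ = classify_motif("clash", distance=2.2)
        og_o = [ia for ia in report.interactions()
                if {ia.atom1, ia.atom2} == {"OG", "O"}]
        assert len(og_o) == 1  # no separate vdW record for the same pair
        assert og_o[0].klass == "hbond" and og_o[0].clash
        assert og_o[0].label() == "hbond*"

    def test_bare_clash_becomes_flagged_vdw(self):
        a = tmpl("ALA", (0, 0, 0), only=["CB"], chain="A")
        b = tmpl("ALA", (0, 0, 2.5), only=["CB"], chain="B")
        report = classify(structure_of(a, b))
        recs = list(report.interactions())
        assert len(recs) == 1
        assert recs[0].klass == "vdw_apolar" and recs[0].clash


class TestProximalAndCompleteness:
    def test_proximal_inside_cutoff(self, classify_motif):
        report, _, _ = classify_motif("proximal", distance=4.8)
        recs = list(report.interactions())
        assert [ia.klass for ia in recs] == ["proximal"]
        assert len(report.pairs) == 1

    def test_nothing_beyond_cutoff(self, classify_motif):
        report, _, _ = classify_motif("proximal", distance=5.2)
        assert report.pairs == []

    def test_far_apart_residues_give_empty_interface(self):
        a = tmpl("GLY", (0, 0, 0), chain="A")
        b = tmpl("GLY", (0, 0, 12.0), chain="B")
        report = classify(structure_of(a, b))
        assert report.pairs == []
        assert report.provenance["empty_interface"]

    def test_every_contact_pair_is_reported(self, mini_complex_16):
        report, _, st = mini_complex_16
        sel = select_partners(st, "A", "B")
        engine = InteractionEngine(st, sel, GeometryConfig())
        contact_keys = {(r1, r2) for r1, r2, _ in engine.residue_contacts()}
        reported = {(p.res1, p.res2) for p in report.pairs}
        assert contact_keys <= reported
        for p in report.pairs:
            assert p.interactions, (p.res1, p.res2)

    def test_exclusivity_one_record_per_direct_pair(self, mini_complex_16):
        report, _, _ = mini_complex_16
        seen = set()
        for ia in report.interactions():
            if ia.mediator is not None:
                continue
            key = (ia.res1, ia.atom1, ia.res2, ia.atom2)
            assert key not in seen
            seen.add(key)


class TestOracleEquivalence:
    def test_residue_contacts_match_brute_force(self, mini_complex_16):
        _, _, st = mini_complex_16
        sel = select_partners(st, "A", "B")
        engine = InteractionEngine(st, sel, GeometryConfig())
        got = {(r1, r2): pytest.approx(d, abs=1e-9)
               for r1, r2, d in engine.residue_contacts()}
        want = {}
        for r1 in engine.side1.residues:
            for r2 in engine.side2.residues:
                dmin = min(
                    (float(np.linalg.norm(a.coords - b.coords))
                     for a in r1.heavy_atoms() for b in r2.heavy_atoms()),
                    default=np.inf)
                if dmin <= 5.0:
                    want[(r1.key, r2.key)] = dmin
        assert set(got) == set(want)
        for k in want:
            assert got[k] == want[k]

    def test_hbond_detector_matches_brute_force(self, mini_complex_16):
        _, _, st = mini_complex_16
        sel = select_partners(st, "A", "B")
        engine = InteractionEngine(st, sel, GeometryConfig())
        got = {(ia.res1, ia.atom1, ia.res2, ia.atom2)
               for ia in engine.detect_hbonds()}
        cfg = engine.config
        want = set()
        for don in engine.side1.heavy + engine.side2.heavy:
            for acc in (engine.side2.heavy
                        if engine.atom_side[don] == 1 else engine.side1.heavy):
                if not (engine.ann[don].is_donor_heavy
                        and engine.ann[acc].is_acceptor):
                    continue
                d = float(np.linalg.norm(don.coords - acc.coords))
                ok, _ = engine._hbond_geometry_ok(don, acc, d)
                if ok and d <= cfg["hbond.da_max"]:
                    a1, a2 = engine._oriented(don, acc)
                    want.add((engine._key(a1), a1.name,
                              engine._key(a2), a2.name))
        assert got == want


class TestInvariances:
    def test_rigid_motion_leaves_report_identical(self):
        pdb_text, _ = make_mini_complex(8, seed=13)
        st1 = parse_structure(pdb_text)
        report1 = classify(st1)
        st2 = parse_structure(pdb_text)
        rng = np.random.default_rng(99)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        for a in st2.atoms():
            a.coords = R @ a.coords + t
        report2 = classify(st2)
        assert report_signature(report1) == report_signature(report2)
        d1 = sorted(round(ia.distance, 6) for ia in report1.interactions())
        d2 = sorted(round(ia.distance, 6) for ia in report2.interactions())
        assert d1 == d2

    def test_enlarging_threshold_never_loses_hbonds(self, mini_complex_16):
        _, _, st = mini_complex_16
        sel = select_partners(st, "A", "B")
        counts = []
        for da in (3.0, 3.3, 3.5, 3.8):
            cfg = GeometryConfig.from_overrides({"hbond.da_max": da})
            engine = InteractionEngine(st, sel, cfg)
            counts.append(len(engine.detect_hbonds()))
        assert counts == sorted(counts)


class TestGeometryConfig:
    def test_override_out_of_range_is_rejected_with_range(self):
        cfg = GeometryConfig()
        with pytest.raises(ConfigError, match=r"\[2\.4, 4\.1\]"):
            cfg.set("hbond.da_max", 9.9)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError, match="unknown parameter"):
            GeometryConfig().set("nope.max", 1.0)

    def test_from_file_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("residue_cutoff = 4.5  # tighter\nhbond.da_max=3.3\n")
        cfg = GeometryConfig.from_file(p)
        assert cfg["residue_cutoff"] == 4.5
        assert cfg["hbond.da_max"] == 3.3

    def test_describe_prints_ranges(self):
        text = GeometryConfig().describe()
        assert "hbond.da_max" in text and "[2.4, 4.1]" in text
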