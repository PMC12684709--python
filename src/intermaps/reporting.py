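"""Tabular and graphical output surfaces derived from an InterfaceReport.

Produces the Table of Atomic Interactions, the two summary tables
(residue-level and by-type), pie-chart fractions, the per-pair interaction
heatmap, and per-class binary layer matrices (the third dimension of the 3D
contact map). All exports are plain TSV/JSON with fixed numeric precision
(distances/areas 2 decimals, angles 1 decimal) so identical runs are
byte-identical.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (DIRECTIONAL_CLASSES, INTERACTION_CLASSES,
                     AtomicInteraction, InterfaceReport)
from .structure import ResidueKey

__all__ = ["SummaryTables", "ContactMaps", "build_interaction_table",
           "summarize", "build_maps", "pie_fractions", "export"]

TABLE_COLUMNS = ["chain1", "resnum1", "icode1", "resname1", "atom1",
                 "chain2", "resnum2", "icode2", "resname2", "atom2",
                 "class", "clash", "distance_A", "angle_deg", "mediator"]


def _res_label(k: ResidueKey) -> str:
    return f"{k.chain_id}:{k.seq_number}{k.insertion_code}:{k.residue_name}"


@dataclass
class SummaryTables:
    residue_pairs: int
    interface_residues: tuple[int, int]
    by_class: dict[str, int]
    clashes_by_class: dict[str, int]
    directional_total: int
    # narrative convention: salt bridges are H-bond-type contacts
    hbonds_including_salt_bridges: int
    total_interactions: int

    def to_dict(self) -> dict:
        return {
            "residue_pairs": self.residue_pairs,
            "interface_residues": {"partner1": self.interface_residues[0],
                                   "partner2": self.interface_residues[1]},
            "by_class": dict(self.by_class),
            "clashes_by_class": dict(self.clashes_by_class),
            "directional_total": self.directional_total,
            "hbonds_including_salt_bridges":
                self.hbonds_including_salt_bridges,
            "total_interactions": self.total_interactions,
        }


@dataclass
class ContactMaps:
    axis1: list[ResidueKey]
    axis2: list[ResidueKey]
    heat: np.ndarray                      # per-pair interaction counts
    layers: dict[str, np.ndarray]         # class -> count matrix
    min_dist: np.ndarray                  # per-pair minimum distances (inf = n/a)

    def labels1(self) -> list[str]:
        return [_res_label(k) for k in self.axis1]

    def labels2(self) -> list[str]:
        return [_res_label(k) for k in self.axis2]


def _row(ia: AtomicInteraction) -> dict:
    med = ""
    if ia.mediator is not None:
        med = f"{_res_label(ia.mediator[0])}/{ia.mediator[1]}"
    return {
        "chain1": ia.res1.chain_id, "resnum1": ia.res1.seq_number,
        "icode1": ia.res1.insertion_code, "resname1": ia.res1.residue_name,
        "atom1": ia.atom1,
        "chain2": ia.res2.chain_id, "resnum2": ia.res2.seq_number,
        "icode2": ia.res2.insertion_code, "resname2": ia.res2.residue_name,
        "atom2": ia.atom2,
        "class": ia.label(), "clash": int(ia.clash),
        "distance_A": round(ia.distance, 2),
        "angle_deg": round(ia.angle, 1) if ia.angle is not None else "",
        "mediator": med,
    }


def build_interaction_table(report: InterfaceReport,
                            classes: list[str] | None = None,
                            residue: ResidueKey | None = None
                            ) -> pd.DataFrame:
    """The Table of Atomic Interactions: one row per atomic interaction,
    grouped by residue pair and sortable by either partner's numbering.
    Clash-flagged interactions carry a '*' suffix on the class name.

    ``classes`` filters by class name; ``residue`` keeps only rows involving
    that residue (either side).
    """
    rows = []
    for pair in report.pairs:
        for ia in pair.interactions:
            if classes and ia.klass not in classes:
                continue
            if residue is not None and not _involves(ia, residue):
                continue
            rows.append(_row(ia))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.sort_values(["chain1", "resnum1", "icode1", "chain2",
                           "resnum2", "icode2", "class"],
                          kind="stable").reset_index(drop=True)


def _involves(ia: AtomicInteraction, key: ResidueKey) -> bool:
    ident = (key.chain_id, key.seq_number, key.insertion_code)
    return ((ia.res1.chain_id, ia.res1.seq_number, ia.res1.insertion_code)
            == ident
            or (ia.res2.chain_id, ia.res2.seq_number, ia.res2.insertion_code)
            == ident)


def summarize(report: InterfaceReport) -> SummaryTables:
    """Residue-level and by-type interaction counts.

    ``directional_total`` counts only geometrically oriented classes (all
    but vdW and proximal); ``hbonds_including_salt_bridges`` reports the
    narrative convention in which salt bridges are counted among H-bonds.
    """
    by_class = {c: 0 for c in INTERACTION_CLASSES}
    clashes = {c: 0 for c in INTERACTION_CLASSES}
    for ia in report.interactions():
        by_class[ia.klass] += 1
        if ia.clash:
            clashes[ia.klass] += 1
    res1 = {(_res_label(ia.res1)) for ia in report.interactions()}
    res2 = {(_res_label(ia.res2)) for ia in report.interactions()}
    directional = sum(by_class[c] for c in DIRECTIONAL_CLASSES)
    total = sum(by_class.values())
    return SummaryTables(
        residue_pairs=len(report.pairs),
        interface_residues=(len(res1), len(res2)),
        by_class=by_class, clashes_by_class=clashes,
        directional_total=directional,
        hbonds_including_salt_bridges=(by_class["hbond"]
                                       + by_class["salt_bridge"]),
        total_interactions=total)


def pie_fractions(report: InterfaceReport,
                  include_proximal: bool | None = None) -> dict[str, float]:
    """Class fractions of the classified atomic interactions (proximal
    excluded by default; config switch ``pie_includes_proximal``)."""
    if include_proximal is None:
        include_proximal = report.config.switches["pie_includes_proximal"]
    counts = {c: 0 for c in INTERACTION_CLASSES}
    for ia in report.interactions():
        counts[ia.klass] += 1
    if not include_proximal:
        counts.pop("proximal")
    total = sum(counts.values())
    if total == 0:
        return {}
    return {c: n / total for c, n in counts.items() if n > 0}


def build_maps(report: InterfaceReport) -> ContactMaps:
    """Contact matrices: residue axes ordered by (chain, number, insertion
    code); ``heat`` counts atomic interactions per residue pair and equals
    the elementwise sum over the per-class layers."""
    keys1 = sorted({p.res1 for p in report.pairs})
    keys2 = sorted({p.res2 for p in report.pairs})
    i1 = {k: i for i, k in enumerate(keys1)}
    i2 = {k: i for i, k in enumerate(keys2)}
    heat = np.zeros((len(keys1), len(keys2)), dtype=int)
    layers = {c: np.zeros((len(keys1), len(keys2)), dtype=int)
              for c in INTERACTION_CLASSES}
    min_dist = np.full((len(keys1), len(keys2)), np.inf)
    for p in report.pairs:
        r, c = i1[p.res1], i2[p.res2]
        min_dist[r, c] = p.min_distance
        for ia in p.interactions:
            heat[r, c] += 1
            layers[ia.klass][r, c] += 1
    return ContactMaps(keys1, keys2, heat, layers, min_dist)


# ---------------------------------------------------------------------------
# file export

def _matrix_tsv(mat: np.ndarray, rows: list[str], cols: list[str],
                fmt=str) -> str:
    lines = ["\t".join([""] + cols)]
    for label, row in zip(rows, mat):
        lines.append("\t".join([label] + [fmt(v) for v in row]))
    return "\n".join(lines) + "\n"


def export(report: InterfaceReport, out_dir: str,
           formats: tuple[str, ...] = ("tsv", "json")) -> dict[str, str]:
    """Write all output surfaces under ``out_dir``; returns the manifest
    (logical name -> path). Supported formats: tsv, json, png (best-effort
    plots requiring matplotlib)."""
    supported = {"tsv", "json", "png"}
    unknown = set(formats) - supported
    if unknown:
        raise ValueError(f"unknown format(s) {sorted(unknown)}; supported: "
                         f"{sorted(supported)}")
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, str] = {}

    def put(name: str, filename: str, content: str):
        path = os.path.join(out_dir, filename)
        with open(path, "w") as fh:
            fh.write(content)
        manifest[name] = path

    summary = summarize(report)
    maps = build_maps(report)

    if "tsv" in formats:
        table = build_interaction_table(report)
        put("interactions", "interactions.tsv",
            table.to_csv(sep="\t", index=False))
        put("heatmap", "heatmap.tsv",
            _matrix_tsv(maps.heat, maps.labels1(), maps.labels2()))
        layer_dir = os.path.join(out_dir, "layers")
        os.makedirs(layer_dir, exist_ok=True)
        for klass, mat in maps.layers.items():
            if mat.sum() == 0:
                continue
            path = os.path.join(layer_dir, f"{klass}.tsv")
            with open(path, "w") as fh:
                fh.write(_matrix_tsv(mat, maps.labels1(), maps.labels2()))
            manifest[f"layer:{klass}"] = path
        put("asa", "asa.tsv", _asa_tsv(report))

    if "json" in formats:
        doc = summary.to_dict()
        if report.sasa is not None:
            doc["bsa"] = {
                "partner1": round(report.sasa.bsa_total_per_partner[0], 2),
                "partner2": round(report.sasa.bsa_total_per_partner[1], 2),
                "interface_area": round(report.sasa.interface_area, 2),
            }
        doc["pie_fractions"] = {k: round(v, 4) for k, v in
                                pie_fractions(report).items()}
        put("summary", "summary.json", json.dumps(doc, indent=2) + "\n")
        put("provenance", "provenance.json",
            json.dumps(report.provenance, indent=2, default=str) + "\n")

    if "png" in formats:
        try:
            _export_plots(report, maps, out_dir, manifest)
        except ImportError:  # plotting is best-effort
            pass
    return manifest


def _asa_tsv(report: InterfaceReport) -> str:
    lines = ["partner\tchain\tresnum\ticode\tresname\tasa_free\t"
             "asa_complex\tbsa"]
    sasa = report.sasa
    if sasa is None:
        return lines[0] + "\n"
    for pname, residues in (("partner1", report.selection.residues1),
                            ("partner2", report.selection.residues2)):
        for r in residues:
            k = r.key
            if k not in sasa.per_residue_free:
                continue
            lines.append(
                f"{pname}\t{k.chain_id}\t{k.seq_number}\t{k.insertion_code}"
                f"\t{k.residue_name}\t{sasa.per_residue_free[k]:.2f}"
                f"\t{sasa.per_residue_complex[k]:.2f}"
                f"\t{sasa.bsa_per_residue[k]:.2f}")
    return "\n".join(lines) + "\n"


def _export_plots(report: InterfaceReport, maps: ContactMaps, out_dir: str,
                  manifest: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = pie_fractions(report)
    if frac:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.pie(list(frac.values()), labels=list(frac.keys()),
               autopct="%1.1f%%")
        ax.set_title("Atomic interactions by class")
        path = os.path.join(out_dir, "pie.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        manifest["pie"] = path
    if maps.heat.size:
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(maps.heat, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(maps.axis2)))
        ax.set_xticklabels(maps.labels2(), rotation=90, fontsize=5)
        ax.set_yticks(range(len(maps.axis1)))
        ax.set_yticklabels(maps.labels1(), fontsize=5)
        fig.colorbar(im, label="atomic interactions")
        fig.tight_layout()
        path = os.path.join(out_dir, "heatmap.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        manifest["heatmap_png"] = path
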