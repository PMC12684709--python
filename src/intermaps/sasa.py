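"""Solvent-accessible and buried surface area.

Shrake-Rupley point sampling on a deterministic golden-spiral (Fibonacci)
lattice: for each atom, test points on its solvent-expanded sphere are
counted accessible when outside every neighbor's expanded sphere, and

    area = 4 pi (r + probe)^2 * accessible / n_points.

Buried surface area (BSA) of a residue is its area in the isolated partner
minus its area in the complex. Hydrogens, waters and ions are excluded by
default so BSA reflects partner-partner burial only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chem import ChemTables
from .structure import Atom, PartnerSelection, Residue, ResidueKey, Structure

__all__ = ["SASAResult", "shrake_rupley", "buried_surface", "fibonacci_sphere"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n points quasi-uniformly covering the unit sphere (golden spiral);
    deterministic, no RNG."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                  n_points: int = 960) -> np.ndarray:
    """Per-atom accessible area (A^2) for atoms at ``coords`` with van der
    Waals ``radii``.

    Cost is O(N * n_points * avg_neighbors) with a KD-tree neighbor cull.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], r=max_reach):
            if j == i:
                continue
            dij = coords[i] - coords[j]
            if float(dij @ dij) >= (expanded[i] + expanded[j]) ** 2:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = (4.0 * math.pi * expanded[i] ** 2
                    * accessible.sum() / n_points)
    return areas


@dataclass
class SASAResult:
    per_residue_complex: dict[ResidueKey, float]
    per_residue_free: dict[ResidueKey, float]
    bsa_per_residue: dict[ResidueKey, float]
    bsa_total_per_partner: tuple[float, float]
    interface_area: float
    interface_residues: tuple[list[ResidueKey], list[ResidueKey]]
    probe_radius: float
    n_points: int
    per_atom_complex: dict = field(default_factory=dict, repr=False)
    per_atom_free: dict = field(default_factory=dict, repr=False)


def _sasa_atoms(residues: list[Residue], tables: ChemTables
                ) -> tuple[list[Atom], list[Residue]]:
    atoms, owners = [], []
    for res in residues:
        for a in res.heavy_atoms():
            atoms.append(a)
            owners.append(res)
    return atoms, owners


def buried_surface(structure: Structure, selection: PartnerSelection,
                   probe: float = 1.4, n_points: int = 960,
                   include_waters: bool = False, bsa_min: float = 0.1,
                   tables: ChemTables | None = None) -> SASAResult:
    """Compute complex and isolated-partner SASA and derive per-residue and
    total buried areas.

    The SASA context is the two partners' heavy atoms only (waters/ions
    excluded unless ``include_waters``), so burial measures partner-partner
    occlusion. ``interface_area`` is the mean of the two partners' buried
    totals.
    """
    tables = tables or ChemTables.default()
    extra: list[Residue] = []
    if include_waters:
        extra = structure.waters()

    a1, o1 = _sasa_atoms(selection.residues1, tables)
    a2, o2 = _sasa_atoms(selection.residues2, tables)
    ax, ox = _sasa_atoms(extra, tables)

    def run(atoms: list[Atom]) -> np.ndarray:
        if not atoms:
            return np.zeros(0)
        coords = np.array([a.coords for a in atoms])
        radii = np.array([tables.vdw(a.element) for a in atoms])
        return shrake_rupley(coords, radii, probe=probe, n_points=n_points)

    area_cplx = run(a1 + a2 + ax)
    area_free1 = run(a1 + ax)
    area_free2 = run(a2 + ax)

    per_atom_complex: dict[Atom, float] = dict(zip(a1 + a2 + ax, area_cplx))
    per_atom_free: dict[Atom, float] = {}
    per_atom_free.update(zip(a1 + ax, area_free1))
    per_atom_free.update(zip(a2 + ax, area_free2))

    per_res_cplx: dict[ResidueKey, float] = {}
    per_res_free: dict[ResidueKey, float] = {}
    for atoms, owners in (((a1 + a2), (o1 + o2)),):
        for a, res in zip(atoms, owners):
            per_res_cplx[res.key] = per_res_cplx.get(res.key, 0.0) \
                + per_atom_complex[a]
            per_res_free[res.key] = per_res_free.get(res.key, 0.0) \
                + per_atom_free[a]

    bsa = {k: per_res_free[k] - per_res_cplx[k] for k in per_res_cplx}
    keys1 = [r.key for r in selection.residues1]
    keys2 = [r.key for r in selection.residues2]
    tot1 = float(sum(bsa[k] for k in keys1))
    tot2 = float(sum(bsa[k] for k in keys2))
    iface1 = [k for k in keys1 if bsa[k] > bsa_min]
    iface2 = [k for k in keys2 if bsa[k] > bsa_min]

    return SASAResult(
        per_residue_complex=per_res_cplx, per_residue_free=per_res_free,
        bsa_per_residue=bsa, bsa_total_per_partner=(tot1, tot2),
        interface_area=0.5 * (tot1 + tot2),
        interface_residues=(iface1, iface2),
        probe_radius=probe, n_points=n_points,
        per_atom_complex=per_atom_complex, per_atom_free=per_atom_free)
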