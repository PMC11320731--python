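"""Geometric pocket characterization: SASA and a grid cavity-volume estimate.

SASA uses the Shrake–Rupley rolling-probe construction: each atom's sphere
of radius (vdW + probe) is covered with quasi-uniform test points and the
exposed fraction scales the full sphere area.  Areas are split into
hydrophobic (C, S) and hydrophilic contributions, which sum exactly to the
total.

The pocket volume estimator counts grid voxels inside a confinement region
that a water-sized probe could occupy (center at least vdW + probe radius
from every receptor atom) while remaining adjacent to the receptor surface;
this replaces alpha-sphere pocket detection with something transparent and
testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confinement import CylinderRegion
from .core_io import ParameterizedSystem, VDW_RADII

__all__ = ["SASAResult", "sasa", "sasa_system", "pocket_volume",
           "sphere_points"]


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


@dataclass
class SASAResult:
    """Solvent-accessible surface areas in Å²."""

    total: float
    hydrophobic: float
    hydrophilic: float
    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int

    def to_csv_row(self) -> dict:
        return {"total_A2": self.total, "hydrophobic_A2": self.hydrophobic,
                "hydrophilic_A2": self.hydrophilic,
                "probe_radius_A": self.probe_radius,
                "n_sphere_points": self.n_sphere_points}


def sasa(positions: np.ndarray,
         radii: np.ndarray,
         hydrophobic: np.ndarray,
         selection: np.ndarray | None = None,
         probe_radius: float = 1.4,
         n_points: int = 960) -> SASAResult:
    """Shrake–Rupley SASA of ``selection`` atoms within the full structure.

    Parameters
    ----------
    positions, radii, hydrophobic:
        Coordinates (n, 3) Å, vdW radii (n,) Å and a boolean hydrophobicity
        flag per atom for the *whole* frame (occluders included).
    selection:
        Indices whose area is reported (default: all atoms).
    probe_radius:
        Solvent probe radius, Å (water: 1.4).
    n_points:
        Test points per atom sphere; area error shrinks as 1/n.
    """
    positions = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    hydrophobic = np.asarray(hydrophobic, bool)
    n = len(positions)
    if n == 0:
        raise ValueError("no atoms given")
    if radii.shape != (n,) or np.any(radii <= 0):
        raise ValueError("every atom needs a positive radius")
    if selection is None:
        selection = np.arange(n)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty selection")

    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    per_atom = np.zeros(selection.size)
    for out_i, i in enumerate(selection):
        ri = expanded[i]
        pts = positions[i] + ri * unit
        # neighbors whose expanded spheres can occlude atom i's test points
        d = np.linalg.norm(positions - positions[i], axis=1)
        neigh = np.nonzero((d < ri + expanded) & (np.arange(n) != i))[0]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            within = np.linalg.norm(pts - positions[j], axis=1) < expanded[j]
            exposed &= ~within
            if not exposed.any():
                break
        per_atom[out_i] = exposed.mean() * 4.0 * np.pi * ri * ri
    phob = float(per_atom[hydrophobic[selection]].sum())
    phil = float(per_atom[~hydrophobic[selection]].sum())
    return SASAResult(total=phob + phil, hydrophobic=phob, hydrophilic=phil,
                      per_atom=per_atom, probe_radius=probe_radius,
                      n_sphere_points=n_points)


def sasa_system(system: ParameterizedSystem,
                selection: np.ndarray | None = None,
                positions: np.ndarray | None = None,
                probe_radius: float = 1.4,
                n_points: int = 960) -> SASAResult:
    """Convenience wrapper computing SASA from a ParameterizedSystem frame."""
    pos = system.positions if positions is None else np.asarray(positions, float)
    radii = system.vdw_radii
    phob = np.array([a.hydrophobic for a in system.atoms])
    return sasa(pos, radii, phob, selection=selection,
                probe_radius=probe_radius, n_points=n_points)


def pocket_volume(frames: np.ndarray,
                  receptor_positions_radii,
                  region: CylinderRegion,
                  spacing: float = 1.0,
                  probe_radius: float = 1.4) -> tuple[float, float]:
    """Grid estimate of the probe-accessible cavity volume inside a region.

    Per frame, a voxel inside ``region`` counts when a probe of radius
    ``probe_radius`` centered there clears every receptor atom
    (center-to-surface gap ≥ probe_radius) while staying within reach of the
    receptor surface (gap ≤ 2·probe_radius + the largest vdW radius present,
    which excludes open solvent far from the protein).  Volume is
    voxel count × spacing³.

    Parameters
    ----------
    frames:
        (n_frames, n_atoms, 3) receptor coordinates, or a single (n_atoms, 3)
        frame.
    receptor_positions_radii:
        vdW radii (n_atoms,) for the receptor atoms.
    Returns
    -------
    (mean volume Å³, SD over frames)
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    radii = np.asarray(receptor_positions_radii, float)
    r_max = radii.max() if radii.size else 1.8

    # voxel lattice covering the region's bounding box
    axis = region.axis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(axis @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    corners = []
    for da in (0.0, region.length):
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                corners.append(region.base_point + da * axis
                               + s1 * region.radius * e1 + s2 * region.radius * e2)
    corners = np.array(corners)
    lo = corners.min(axis=0)
    hi = corners.max(axis=0)
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    rel = centers - region.base_point
    a = rel @ axis
    r_perp = np.linalg.norm(rel - np.outer(a, axis), axis=1)
    inside = (a >= 0) & (a <= region.length) & (r_perp <= region.radius)
    centers = centers[inside]
    if centers.size == 0:
        return 0.0, 0.0

    vols = []
    reach = 2.0 * probe_radius + r_max
    for frame in frames:
        if frame.shape[0] == 0:
            vols.append(0.0)
            continue
        d = np.linalg.norm(centers[:, None] - frame[None], axis=-1)
        gap = (d - radii[None]).min(axis=1)
        ok = (gap >= probe_radius) & (gap <= reach)
        vols.append(float(ok.sum()) * spacing ** 3)
    vols = np.asarray(vols)
    return float(vols.mean()), float(vols.std(ddof=0))
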