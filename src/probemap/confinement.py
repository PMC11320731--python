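"""Cylinder-shaped flat-bottom harmonic wall restraint.

Probes sample freely inside a semiclosed cylinder anchored over a chosen
receptor face; excursions beyond the curved wall or the far (closed) cap pay
a half-harmonic penalty.  The face of the cylinder that touches the receptor
is open — the receptor itself blocks escape there — so no penalty is applied
for negative axial coordinates.

The energy is C¹ everywhere: for a point at perpendicular distance r⊥ from
the axis and signed axial coordinate a (measured from the open-face center,
positive away from the receptor),

    E = ½ k [max(0, r⊥ − R)² + max(0, a − L)²]      (closed far end)

with force −∇E.  Inside the cylinder E = 0 and the force vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import ParameterizedSystem

__all__ = ["CylinderRegion", "region_from_residues", "wall_energy_force",
           "wall_energy_force_batch", "contains"]


@dataclass
class CylinderRegion:
    """Confinement geometry plus wall stiffness.

    ``base_point`` is the center of the open face (the receptor side);
    ``axis`` is a unit vector pointing away from the receptor.
    """

    base_point: np.ndarray
    axis: np.ndarray
    radius: float
    length: float
    k_wall: float = 10.0       # kcal mol^-1 Å^-2
    closed_far_end: bool = True

    def __post_init__(self) -> None:
        self.base_point = np.asarray(self.base_point, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        norm = np.linalg.norm(self.axis)
        if abs(norm - 1.0) > 1e-9:
            if norm < 1e-12:
                raise ValueError("axis must be a nonzero vector")
            self.axis = self.axis / norm
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.k_wall < 0:
            raise ValueError("k_wall must be >= 0")

    def to_dict(self) -> dict:
        return {
            "base_point": self.base_point.tolist(),
            "axis": self.axis.tolist(),
            "radius": self.radius,
            "length": self.length,
            "k_wall": self.k_wall,
            "closed_far_end": self.closed_far_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CylinderRegion":
        return cls(
            base_point=np.asarray(d["base_point"], float),
            axis=np.asarray(d["axis"], float),
            radius=float(d["radius"]),
            length=float(d["length"]),
            k_wall=float(d.get("k_wall", 10.0)),
            closed_far_end=bool(d.get("closed_far_end", True)))


def region_from_residues(system: ParameterizedSystem,
                         residue_keys: Sequence[tuple[str, int]],
                         radius: float | None = None,
                         length: float = 15.0,
                         k_wall: float = 10.0) -> CylinderRegion:
    """Anchor a cylinder over the pocket defined by ``residue_keys``.

    The base point is the centroid of the anchor residues' heavy atoms and
    the axis runs from the receptor center of geometry through that centroid,
    pointing outward.  When ``radius`` is None it is sized from the anchors:
    half the maximum pairwise anchor-centroid distance plus 6 Å.
    """
    if not residue_keys:
        raise ValueError("at least one anchor residue is required")
    centroids = []
    all_anchor = []
    for key in residue_keys:
        idx = system.residue_atoms(tuple(key), heavy_only=True)
        if len(idx) == 0:
            raise ValueError(f"residue {key!r} has no heavy atoms")
        pos = np.array([system.atoms[i].position for i in idx])
        centroids.append(pos.mean(axis=0))
        all_anchor.append(pos)
    centroids = np.array(centroids)
    base_point = np.vstack(all_anchor).mean(axis=0)

    rec_idx = system.receptor_indices
    heavy = [i for i in rec_idx if system.atoms[i].is_heavy]
    center = np.array([system.atoms[i].position for i in heavy]).mean(axis=0)
    direction = base_point - center
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("anchor centroid coincides with the receptor center; "
                         "cannot orient the cylinder axis")
    axis = direction / norm

    if radius is None:
        if len(centroids) > 1:
            d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
            radius = float(d.max()) / 2.0 + 6.0
        else:
            radius = 6.0
    return CylinderRegion(base_point=base_point, axis=axis, radius=radius,
                          length=length, k_wall=k_wall)


def wall_energy_force_batch(positions: np.ndarray,
                            region: CylinderRegion) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized wall energy/force for an (n, 3) array of positions.

    Returns ``(energies (n,), forces (n, 3))`` in kcal/mol and
    kcal mol⁻¹ Å⁻¹.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    rel = pos - region.base_point
    a = rel @ region.axis                       # signed axial coordinate
    radial_vec = rel - np.outer(a, region.axis)
    r = np.linalg.norm(radial_vec, axis=1)

    k = region.k_wall
    d_rad = np.maximum(0.0, r - region.radius)
    energy = 0.5 * k * d_rad ** 2
    forces = np.zeros_like(pos)
    out = d_rad > 0
    if np.any(out):
        unit = radial_vec[out] / r[out, None]
        forces[out] -= (k * d_rad[out])[:, None] * unit

    if region.closed_far_end:
        d_ax = np.maximum(0.0, a - region.length)
        energy += 0.5 * k * d_ax ** 2
        forces -= np.outer(k * d_ax, region.axis)
    # open face (a < 0): no penalty — the receptor blocks escape there
    return energy, forces


def wall_energy_force(position: np.ndarray,
                      region: CylinderRegion) -> tuple[float, np.ndarray]:
    """Wall energy (kcal/mol) and force (kcal mol⁻¹ Å⁻¹) at a single point."""
    e, f = wall_energy_force_batch(np.asarray(position, float).reshape(1, 3), region)
    return float(e[0]), f[0]


def contains(region: CylinderRegion, position: np.ndarray) -> bool:
    """True iff the wall energy vanishes at ``position`` and the point is on
    the sampling side of the open face (axial coordinate ≥ 0)."""
    pos = np.asarray(position, dtype=float).reshape(3)
    rel = pos - region.base_point
    a = float(rel @ region.axis)
    if a < 0:
        return False
    r = float(np.linalg.norm(rel - a * region.axis))
    if r > region.radius:
        return False
    if region.closed_far_end and a > region.length:
        return False
    return True
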