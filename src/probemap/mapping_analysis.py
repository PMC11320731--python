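"""Trajectory analyses for probe-confined mapping.

Implements the statistics used to read binding-site hotspots out of a probe
trajectory:

* pocket occupancy — % of frames with any probe heavy atom within a cutoff
  (default 4 Å) of designated pocket-center residues (defaults: generic
  positions 2.43, 7.56 and 8.48);
* frame-averaged probe density on a voxel grid (default 1 Å cell side),
  thresholded at an isovalue (default 0.5);
* per-residue electrostatic / van der Waals interaction energies with a
  probe, for residues within 5 Å of the probe, averaged over contributing
  frames — the hotspot table;
* hydrogen bonds (3.5 Å donor–acceptor distance, 90° D–H···A angle cutoff),
  contact frequency (e.g. the 3.49–3.50 ionic lock), RMSF and RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import BWMap, ParameterizedSystem, Trajectory, VDW_RADII
from .probe_sampler import NonbondedModel, nonbonded_energy

__all__ = [
    "OccupancyResult", "DensityGrid", "pocket_occupancy", "density_grid",
    "threshold_density", "residue_interaction_energies", "rank_hotspots",
    "hydrogen_bonds", "contact_frequency", "rmsf", "rmsd_series",
    "kabsch", "DEFAULT_CENTER_LABELS",
]

#: Generic residue positions defining the intracellular pocket center.
DEFAULT_CENTER_LABELS = ("2.43", "7.56", "8.48")


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyResult:
    """Pocket occupancy: fraction of frames with at least one probe present."""

    percent_frames_occupied: float
    per_frame_flags: np.ndarray
    cutoff: float
    center_residues: tuple[str, ...]

    def to_csv(self, path: str | Path) -> None:
        header = (f"# pocket occupancy; cutoff={self.cutoff} A; "
                  f"centers={','.join(self.center_residues)}\n"
                  f"# percent_frames_occupied={self.percent_frames_occupied}\n")
        df = pd.DataFrame({"frame": np.arange(len(self.per_frame_flags)),
                           "occupied": self.per_frame_flags.astype(int)})
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)


def _resolve_center_indices(system: ParameterizedSystem,
                            center_residues, bw_map: BWMap | None) -> np.ndarray:
    """Resolve center residues (BW labels or (chain, resid) keys) to heavy-atom
    indices."""
    idx: list[int] = []
    for item in center_residues:
        if isinstance(item, str):
            if bw_map is None:
                raise ValueError("a BWMap is required to resolve label "
                                 f"{item!r}")
            found = [key for key, lab in bw_map.forward.items() if lab == item]
            if not found:
                raise KeyError(f"no residue annotated as {item!r}")
            keys = found
        else:
            keys = [tuple(item)]
        for key in keys:
            idx.extend(system.residue_atoms(key, heavy_only=True))
    return np.asarray(sorted(set(idx)), dtype=int)


def pocket_occupancy(traj: Trajectory,
                     probe_selection: np.ndarray | None = None,
                     center_residues=DEFAULT_CENTER_LABELS,
                     bw_map: BWMap | None = None,
                     cutoff: float = 4.0) -> OccupancyResult:
    """Percentage of frames with any probe heavy atom within ``cutoff`` of
    any heavy atom of any pocket-center residue.

    ``center_residues`` may mix Ballesteros–Weinstein labels (resolved via
    ``bw_map``) and explicit ``(chain, residue_id)`` keys.
    """
    system = traj.system
    if probe_selection is None:
        probe_selection = system.probe_indices
    probe_selection = np.asarray(probe_selection, dtype=int)
    heavy = system.heavy_mask
    probe_heavy = probe_selection[heavy[probe_selection]]
    if probe_heavy.size == 0:
        raise ValueError("probe selection contains no heavy atoms")
    center_idx = _resolve_center_indices(system, center_residues, bw_map)
    if center_idx.size == 0:
        raise ValueError("no pocket-center atoms resolved")

    flags = np.empty(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        d = np.linalg.norm(
            traj.frames[f, probe_heavy][:, None]
            - traj.frames[f, center_idx][None], axis=-1)
        flags[f] = bool((d <= cutoff).any())
    percent = 100.0 * flags.sum() / traj.n_frames
    labels = tuple(str(c) for c in center_residues)
    return OccupancyResult(percent_frames_occupied=percent,
                           per_frame_flags=flags, cutoff=cutoff,
                           center_residues=labels)


# ---------------------------------------------------------------------------
# Density grid
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Axis-aligned voxel grid of frame-averaged occupancy in [0, 1]."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.values = np.asarray(self.values, float).reshape(self.shape)
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("density values must lie in [0, 1]")

    def voxel_centers(self) -> np.ndarray:
        axes = [self.origin[d] + self.spacing * (np.arange(self.shape[d]) + 0.5)
                for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def write_dx(self, path: str | Path) -> None:
        """Write the grid as an OpenDX scalar field (VMD/PyMOL readable)."""
        nx, ny, nz = self.shape
        # OpenDX convention: positions are voxel centers
        o = self.origin + 0.5 * self.spacing
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}\n",
            f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n",
            f"delta {self.spacing:.6f} 0.000000 0.000000\n",
            f"delta 0.000000 {self.spacing:.6f} 0.000000\n",
            f"delta 0.000000 0.000000 {self.spacing:.6f}\n",
            f"object 2 class gridconnections counts {nx} {ny} {nz}\n",
            f"object 3 class array type double rank 0 items {nx * ny * nz} "
            "data follows\n",
        ]
        flat = self.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            chunk = flat[i:i + 3]
            lines.append(" ".join(f"{v:.6e}" for v in chunk) + "\n")
        lines.append('attribute "dep" string "positions"\n'
                     'object "density" class field\n')
        Path(path).write_text("".join(lines))


def density_grid(traj: Trajectory,
                 selection: np.ndarray | None = None,
                 spacing: float = 1.0,
                 pad: float = 2.0,
                 radii: dict[str, float] | None = None) -> DensityGrid:
    """Frame-averaged binary occupancy on a voxel grid.

    Per frame, a voxel is occupied iff its center lies within the van der
    Waals radius of any selected atom; the grid value is the fraction of
    frames in which the voxel was occupied.  The grid spans the selection's
    bounding box over all frames plus ``pad`` Å.
    """
    system = traj.system
    if selection is None:
        selection = system.probe_indices
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection for density grid")
    if radii is None:
        radii = VDW_RADII
    atom_radii = np.array([radii.get(system.atoms[i].element, 1.7)
                           for i in selection])

    sel_coords = traj.frames[:, selection, :]
    lo = sel_coords.reshape(-1, 3).min(axis=0) - pad - atom_radii.max()
    hi = sel_coords.reshape(-1, 3).max(axis=0) + pad + atom_radii.max()
    if np.any(hi <= lo):
        raise ValueError("zero-extent selection bounding box")
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) for d in range(3))
    counts = np.zeros(shape, dtype=np.int64)

    nx, ny, nz = shape
    for f in range(traj.n_frames):
        occ = np.zeros(shape, dtype=bool)
        for coord, r in zip(sel_coords[f], atom_radii):
            # local sub-box around the atom
            i0 = np.maximum(0, np.floor((coord - r - lo) / spacing - 0.5).astype(int))
            i1 = np.minimum(shape, np.ceil((coord + r - lo) / spacing + 0.5).astype(int))
            if np.any(i1 <= i0):
                continue
            ax = [lo[d] + spacing * (np.arange(i0[d], i1[d]) + 0.5) - coord[d]
                  for d in range(3)]
            d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                  + ax[2][None, None, :] ** 2)
            occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
        counts += occ
    return DensityGrid(origin=lo, spacing=spacing, shape=shape,
                       values=counts / traj.n_frames)


@dataclass
class ThresholdResult:
    """Voxels at or above an isovalue, with their count and centroid."""

    indices: np.ndarray          # (n, 3) integer voxel indices
    centers: np.ndarray          # (n, 3) Å
    isovalue: float

    @property
    def count(self) -> int:
        return len(self.indices)

    @property
    def centroid(self) -> np.ndarray | None:
        return self.centers.mean(axis=0) if self.count else None


def threshold_density(grid: DensityGrid, isovalue: float = 0.5) -> ThresholdResult:
    """Voxels with value ≥ isovalue (and strictly > 0, so an isovalue of 0
    selects only visited voxels)."""
    mask = (grid.values >= isovalue) & (grid.values > 0)
    idx = np.argwhere(mask)
    centers = grid.origin + grid.spacing * (idx + 0.5)
    return ThresholdResult(indices=idx, centers=centers, isovalue=isovalue)


def threshold_to_pdb(result: ThresholdResult, path: str | Path) -> None:
    """Export suprathreshold voxel centers as pseudo-atom ATOM records."""
    lines = []
    for i, (x, y, z) in enumerate(result.centers, start=1):
        lines.append(
            f"ATOM  {i % 100000:5d}  DUM DEN A{(i - 1) % 9999 + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           D\n")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Per-residue interaction energies (hotspots)
# ---------------------------------------------------------------------------

def residue_interaction_energies(traj: Trajectory,
                                 probe_group: np.ndarray | None = None,
                                 model: NonbondedModel | None = None,
                                 cutoff: float = 5.0,
                                 bw_map: BWMap | None = None,
                                 average_over: str = "contributing"
                                 ) -> pd.DataFrame:
    """Per-residue electrostatic / van der Waals energies with a probe group.

    In each frame, every receptor residue with at least one heavy atom
    within ``cutoff`` Å of any probe atom contributes its full
    residue–probe pairwise energy.  The table reports means ± SD either over
    contributing frames only (default — averaging zeros over all frames
    would dilute hotspots) or over all frames (``average_over="all"``).

    Columns: chain, residue_id, residue_name, bw, elec_mean, elec_sd,
    vdw_mean, vdw_sd, total_mean, n_frames.
    """
    system = traj.system
    if probe_group is None:
        probe_group = system.probe_indices
    probe_group = np.asarray(probe_group, dtype=int)
    if probe_group.size == 0:
        raise ValueError("empty probe group")
    if model is None:
        model = NonbondedModel()
    if average_over not in ("contributing", "all"):
        raise ValueError("average_over must be 'contributing' or 'all'")

    # parameter check: analysis needs charges/LJ everywhere
    missing = [i for i in range(system.n_atoms)
               if system.atoms[i].lj_rmin_half == 0.0
               and system.atoms[i].lj_epsilon == 0.0
               and system.atoms[i].charge == 0.0
               and not system.atoms[i].is_probe]
    rec_keys = [k for k in system.residue_keys
                if not any(system.atoms[i].is_probe for i in system.residues[k])]
    if len(missing) == len(system.receptor_indices) and len(missing) > 0:
        raise ValueError(
            "receptor atoms are unparameterized (no charges or LJ terms); "
            f"first offenders: {missing[:5]}")

    qp = np.array([system.atoms[i].charge for i in probe_group])
    ep = np.array([system.atoms[i].lj_epsilon for i in probe_group])
    rp = np.array([system.atoms[i].lj_rmin_half for i in probe_group])

    res_atoms = {k: system.residues[k] for k in rec_keys}
    res_heavy = {k: system.residue_atoms(k, heavy_only=True) for k in rec_keys}
    res_params = {
        k: (np.array([system.atoms[i].charge for i in res_atoms[k]]),
            np.array([system.atoms[i].lj_epsilon for i in res_atoms[k]]),
            np.array([system.atoms[i].lj_rmin_half for i in res_atoms[k]]))
        for k in rec_keys}

    acc: dict[tuple[str, int], list[tuple[float, float]]] = {k: [] for k in rec_keys}
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        xp = frame[probe_group]
        for k in rec_keys:
            hv = res_heavy[k]
            if hv.size == 0:
                continue
            if np.isfinite(cutoff):
                d = np.linalg.norm(frame[hv][:, None] - xp[None], axis=-1)
                if d.min() > cutoff:
                    if average_over == "all":
                        acc[k].append((0.0, 0.0))
                    continue
            q, e, r = res_params[k]
            elec, vdw = nonbonded_energy(frame[res_atoms[k]], q, e, r,
                                         xp, qp, ep, rp, model)
            acc[k].append((elec, vdw))

    rows = []
    for k in rec_keys:
        if not acc[k]:
            continue
        arr = np.asarray(acc[k])
        chain, resid = k
        rows.append({
            "chain": chain,
            "residue_id": resid,
            "residue_name": system.atoms[int(res_atoms[k][0])].residue_name,
            "bw": bw_map.label(chain, resid) if bw_map else None,
            "elec_mean": arr[:, 0].mean(),
            "elec_sd": arr[:, 0].std(ddof=0),
            "vdw_mean": arr[:, 1].mean(),
            "vdw_sd": arr[:, 1].std(ddof=0),
            "total_mean": arr.sum(axis=1).mean(),
            "n_frames": len(arr),
        })
    return pd.DataFrame(rows, columns=[
        "chain", "residue_id", "residue_name", "bw", "elec_mean", "elec_sd",
        "vdw_mean", "vdw_sd", "total_mean", "n_frames"])


def rank_hotspots(table: pd.DataFrame, key: str = "total") -> pd.DataFrame:
    """Sort the hotspot table most-favorable (most negative mean energy)
    first; ties broken by ascending residue id.

    ``key`` is ``"electrostatic"``, ``"vdw"`` or ``"total"``.
    """
    columns = {"electrostatic": "elec_mean", "elec": "elec_mean",
               "vdw": "vdw_mean", "total": "total_mean"}
    if key not in columns:
        raise ValueError(f"unknown ranking key {key!r}; "
                         f"choose from {sorted(set(columns))}")
    if table.empty:
        raise ValueError("hotspot table is empty")
    return (table.sort_values([columns[key], "residue_id"],
                              ascending=[True, True])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Hydrogen bonds and contacts
# ---------------------------------------------------------------------------

def hydrogen_bonds(traj: Trajectory,
                   donors: Sequence[tuple[int, int]],
                   acceptors: Sequence[int],
                   d_cut: float = 3.5,
                   angle_cut: float = 90.0) -> pd.DataFrame:
    """Per donor–acceptor pair fraction of frames with a hydrogen bond.

    A bond is present when the donor–acceptor distance is ≤ ``d_cut`` Å and
    the D–H···A angle is ≥ ``angle_cut`` degrees (the angle at the hydrogen;
    180° is linear).  ``donors`` is a sequence of ``(donor_atom, hydrogen)``
    index pairs — a donor without a recorded hydrogen is an error.
    """
    system = traj.system
    for d, h in donors:
        if h is None:
            raise ValueError(f"donor atom {d} has no attached hydrogen recorded")
        if system.atoms[h].element != "H":
            raise ValueError(f"atom {h} recorded as hydrogen of donor {d} "
                             f"is element {system.atoms[h].element!r}")
    rows = []
    for (d, h) in donors:
        for a in acceptors:
            if a == d:
                continue
            present = 0
            for f in range(traj.n_frames):
                xd, xh, xa = traj.frames[f, d], traj.frames[f, h], traj.frames[f, a]
                if np.linalg.norm(xd - xa) > d_cut:
                    continue
                v1 = xd - xh
                v2 = xa - xh
                cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_cut:
                    present += 1
            rows.append({"donor": d, "hydrogen": h, "acceptor": a,
                         "fraction": present / traj.n_frames})
    return pd.DataFrame(rows, columns=["donor", "hydrogen", "acceptor",
                                       "fraction"])


def contact_frequency(traj: Trajectory,
                      group_a: np.ndarray,
                      group_b: np.ndarray,
                      d_cut: float = 4.0,
                      heavy_only: bool = True) -> float:
    """Fraction of frames in which the minimum heavy-atom distance between
    two groups is ≤ ``d_cut`` Å (e.g. the 3.49–3.50 ionic-lock contact)."""
    system = traj.system
    group_a = np.asarray(group_a, int)
    group_b = np.asarray(group_b, int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("contact groups must be nonempty")
    if heavy_only:
        heavy = system.heavy_mask
        group_a = group_a[heavy[group_a]]
        group_b = group_b[heavy[group_b]]
        if group_a.size == 0 or group_b.size == 0:
            raise ValueError("contact groups contain no heavy atoms")
    hits = 0
    for f in range(traj.n_frames):
        d = np.linalg.norm(traj.frames[f, group_a][:, None]
                           - traj.frames[f, group_b][None], axis=-1)
        if d.min() <= d_cut:
            hits += 1
    return hits / traj.n_frames


# ---------------------------------------------------------------------------
# RMSF / RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto reference
    (proper rotation only; reflections rejected).  Returns (R, t) with
    aligned = mobile @ R.T + t."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ mc
    return rot, t


def rmsf(traj: Trajectory,
         selection: np.ndarray | None = None,
         align: bool = True,
         per_residue: bool = True):
    """Root-mean-square fluctuation about the mean structure.

    Frames are optionally superposed (Kabsch, heavy atoms of the selection)
    onto the mean structure before computing
    RMSF_i = sqrt(<|x_i - <x_i>|^2>).  Returns per-atom values, or a
    DataFrame of per-residue means over heavy atoms when ``per_residue``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    system = traj.system
    if selection is None:
        selection = system.receptor_indices
    selection = np.asarray(selection, int)
    coords = traj.frames[:, selection, :].copy()

    if align:
        mean = coords.mean(axis=0)
        for _ in range(2):  # align -> new mean -> realign (converges fast)
            for f in range(coords.shape[0]):
                rot, t = kabsch(coords[f], mean)
                coords[f] = coords[f] @ rot.T + t
            mean = coords.mean(axis=0)
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))

    if not per_residue:
        return per_atom
    rows = []
    for key in system.residue_keys:
        atom_idx = system.residue_atoms(key, heavy_only=True)
        local = np.nonzero(np.isin(selection, atom_idx))[0]
        if local.size == 0:
            continue
        rows.append({"chain": key[0], "residue_id": key[1],
                     "rmsf": float(per_atom[local].mean())})
    return pd.DataFrame(rows, columns=["chain", "residue_id", "rmsf"])


def rmsd_series(traj: Trajectory,
                reference: int | np.ndarray = 0,
                selection: np.ndarray | None = None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) of ``selection`` to a reference frame (index or an
    explicit coordinate array), with optional Kabsch superposition."""
    system = traj.system
    if selection is None:
        selection = np.arange(system.n_atoms)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("selection must be nonempty")
    ref = (traj.frames[reference, selection]
           if isinstance(reference, (int, np.integer))
           else np.asarray(reference, float))
    if ref.shape != (selection.size, 3):
        raise ValueError(
            f"reference shape {ref.shape} does not match selection "
            f"({selection.size} atoms)")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.frames[f, selection]
        if superpose:
            rot, t = kabsch(x, ref)
            x = x @ rot.T + t
        out[f] = np.sqrt(((x - ref) ** 2).sum(axis=1).mean())
    return out
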