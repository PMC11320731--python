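"""Langevin dynamics of rigid probe molecules around a fixed receptor.

This is a desk-scale sampling engine for the probe-confined mapping
protocol: probe molecules move as rigid bodies (translation + rotation)
under Coulomb and Lennard-Jones forces from a rigid receptor and from each
other, plus the cylindrical flat-bottom wall of :mod:`probemap.confinement`.
Solvent and membrane are implicit in the dielectric constant and the
Langevin friction; there are no periodic boundaries.

Units: Å, ps, amu, kcal/mol, elementary charges.  Forces in
kcal mol⁻¹ Å⁻¹ are converted to accelerations with
1 kcal/mol = 418.4 amu Å² ps⁻².

The integrator is a BAOAB splitting (half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick).  Rotations use
quaternions with the body-frame inertia tensor diagonalized once per probe
template; the inertial (Euler) coupling term is dropped, which is a standard
simplification for thermostatted rigid-body sampling at moderate friction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .confinement import CylinderRegion, contains, wall_energy_force_batch
from .core_io import (KB_KCAL, AtomRecord, ParameterizedSystem, ProbeTemplate,
                      RunConfig, Trajectory)

KCAL_TO_AKMA = 418.4  # kcal/mol -> amu Å² ps⁻²

__all__ = ["NonbondedModel", "ProbeState", "pair_energy", "nonbonded_energy",
           "attach_probes", "place_probes", "run_langevin"]


@dataclass
class NonbondedModel:
    """Coulomb + Lennard-Jones pairwise model.

    Electrostatics: ``k_c q_i q_j / (ε r)`` with k_c = 332.0637
    kcal Å mol⁻¹ e⁻².  Lennard-Jones in Rmin form with Lorentz–Berthelot
    combination (ε_ij geometric mean, Rmin_ij sum of half-radii).  Pairs
    beyond ``cutoff`` are excluded; with ``switching`` on, energies are
    multiplied by a CHARMM-style switching function between ``switch_start``
    and ``cutoff`` so both energy and force go smoothly to zero.
    """

    coulomb_constant: float = 332.0637
    dielectric: float = 1.0
    cutoff: float = 12.0
    switching: bool = False
    switch_start: float = 10.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")
        if self.switching and not (0 < self.switch_start < self.cutoff):
            raise ValueError("switch_start must lie in (0, cutoff)")


def _switch(r: np.ndarray, model: NonbondedModel) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM switching function S(r) and its derivative dS/dr."""
    ron2, roff2 = model.switch_start ** 2, model.cutoff ** 2
    denom = (roff2 - ron2) ** 3
    r2 = r ** 2
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > model.switch_start) & (r <= model.cutoff)
    rm2 = r2[mid]
    s[mid] = (roff2 - rm2) ** 2 * (roff2 + 2 * rm2 - 3 * ron2) / denom
    ds[mid] = 12 * r[mid] * (roff2 - rm2) * (ron2 - rm2) / denom
    s[r > model.cutoff] = 0.0
    return s, ds


def nonbonded_energy(xa: np.ndarray, qa: np.ndarray, ea: np.ndarray, ra: np.ndarray,
                     xb: np.ndarray, qb: np.ndarray, eb: np.ndarray, rb: np.ndarray,
                     model: NonbondedModel,
                     forces: bool | str = False):
    """Pairwise Coulomb + LJ between two atom sets (array form).

    Parameters are positions (n,3), charges, LJ well depths and Rmin/2 for
    each set.  Returns ``(elec, vdw)`` in kcal/mol, plus per-atom forces on
    set *a* (kcal mol⁻¹ Å⁻¹) when ``forces`` is True.

    Raises :class:`ValueError` naming the pair if two atoms overlap
    (r < 1e-6 Å).
    """
    xa = np.atleast_2d(xa)
    xb = np.atleast_2d(xb)
    if xa.size == 0 or xb.size == 0:
        z = np.zeros_like(xa)
        return (0.0, 0.0, z) if forces else (0.0, 0.0)
    disp = xa[:, None, :] - xb[None, :, :]
    r = np.linalg.norm(disp, axis=-1)
    if np.any(r < 1e-6):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ValueError(
            f"overlapping atoms: pair ({i}, {j}) at r = {r[i, j]:.2e} Å")

    within = r <= model.cutoff
    inv_r = np.where(within, 1.0 / r, 0.0)

    kc = model.coulomb_constant / model.dielectric
    qq = np.asarray(qa)[:, None] * np.asarray(qb)[None, :]
    u_elec = kc * qq * inv_r

    eps = np.sqrt(np.asarray(ea)[:, None] * np.asarray(eb)[None, :])
    rmin = np.asarray(ra)[:, None] + np.asarray(rb)[None, :]
    ratio6 = np.where(within, (rmin * inv_r) ** 6, 0.0)
    u_vdw = eps * (ratio6 ** 2 - 2.0 * ratio6)

    if model.switching:
        s, ds = _switch(r, model)
        u_elec_s = u_elec * s
        u_vdw_s = u_vdw * s
    else:
        u_elec_s, u_vdw_s = u_elec, u_vdw

    elec = float(u_elec_s.sum())
    vdw = float(u_vdw_s.sum())
    if not forces:
        return elec, vdw

    # dU/dr for the unswitched terms
    du_elec = -u_elec * inv_r
    du_vdw = -12.0 * eps * inv_r * (ratio6 ** 2 - ratio6)
    if model.switching:
        du = (du_elec + du_vdw) * s + (u_elec + u_vdw) * ds
    else:
        du = du_elec + du_vdw
    # force on a = -dU/dr * rhat, rhat = disp / r
    f_pair = np.where(within, -du * inv_r, 0.0)[:, :, None] * disp
    f_on_a = f_pair.sum(axis=1)
    if forces == "both":
        return elec, vdw, f_on_a, -f_pair.sum(axis=0)
    return elec, vdw, f_on_a


def _unpack(atoms, positions=None):
    """Accept a list of AtomRecord or a (system, indices) pair."""
    if isinstance(atoms, tuple) and isinstance(atoms[0], ParameterizedSystem):
        system, idx = atoms
        idx = np.asarray(idx, dtype=int)
        recs = [system.atoms[i] for i in idx]
    else:
        recs = list(atoms)
    x = (np.array([a.position for a in recs], dtype=float)
         if positions is None else np.asarray(positions, float))
    q = np.array([a.charge for a in recs])
    e = np.array([a.lj_epsilon for a in recs])
    r = np.array([a.lj_rmin_half for a in recs])
    return x, q, e, r


def pair_energy(atoms_a, atoms_b, model: NonbondedModel,
                positions_a: np.ndarray | None = None,
                positions_b: np.ndarray | None = None) -> tuple[float, float]:
    """Electrostatic and van der Waals interaction energy between two atom
    groups, in kcal/mol.

    ``atoms_a``/``atoms_b`` are lists of :class:`AtomRecord` or
    ``(system, indices)`` pairs; ``positions_*`` override stored coordinates
    (for per-frame trajectory analysis).
    """
    xa, qa, ea, ra = _unpack(atoms_a, positions_a)
    xb, qb, eb, rb = _unpack(atoms_b, positions_b)
    return nonbonded_energy(xa, qa, ea, ra, xb, qb, eb, rb, model)


# ---------------------------------------------------------------------------
# Probe setup
# ---------------------------------------------------------------------------

def attach_probes(system: ParameterizedSystem, template: ProbeTemplate,
                  n_copies: int) -> ParameterizedSystem:
    """Return a new system with ``n_copies`` of the probe template appended
    as probe groups (coordinates are placeholders until placement)."""
    atoms = [AtomRecord(**{f: getattr(a, f) for f in (
        "serial", "name", "element", "residue_name", "residue_id", "chain",
        "charge", "lj_epsilon", "lj_rmin_half", "mass", "is_probe")},
        position=a.position.copy()) for a in system.atoms]
    probes = [g.copy() for g in system.probes]
    next_resid = max((a.residue_id for a in atoms), default=0) + 1
    next_serial = max((a.serial for a in atoms), default=0) + 1
    resname = template.name[:3].upper() or "PRB"
    n0 = len(atoms)
    for c in range(n_copies):
        new = template.to_atoms(residue_id=next_resid + c, chain="P",
                                residue_name=resname,
                                serial_start=next_serial)
        next_serial += len(new)
        probes.append(np.arange(n0, n0 + len(new)))
        atoms.extend(new)
        n0 += len(new)
    return ParameterizedSystem(atoms, probes)


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    u1, u2, u3 = rng.random(3)
    return np.array([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3)])


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ax, ay, az, aw = a
    bx, by, bz, bw = b
    return np.array([
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
        aw * bw - ax * bx - ay * by - az * bz])


def place_probes(system: ParameterizedSystem, region: CylinderRegion,
                 seed: int, min_separation: float = 2.5,
                 max_attempts_per_probe: int = 2000) -> ParameterizedSystem:
    """Place every probe at a random position/orientation inside the region.

    Postconditions: all probe centers of mass satisfy
    :func:`~probemap.confinement.contains`; all probe–probe and
    probe–receptor heavy-atom distances are at least ``min_separation``.
    Deterministic for a given seed.  Raises :class:`RuntimeError` when the
    attempt budget is exhausted.
    """
    rng = np.random.default_rng(seed)
    rec_idx = [i for i in system.receptor_indices if system.atoms[i].is_heavy]
    rec_pos = (np.array([system.atoms[i].position for i in rec_idx])
               if rec_idx else np.zeros((0, 3)))

    # orthonormal frame for the cylinder cross-section
    axis = region.axis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(axis @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    placed_heavy: list[np.ndarray] = []
    new_positions = system.positions
    for group in system.probes:
        masses = np.array([system.atoms[i].mass for i in group])
        body = np.array([system.atoms[i].position for i in group])
        body = body - masses @ body / masses.sum()
        heavy_local = np.array([system.atoms[i].is_heavy for i in group])
        for attempt in range(max_attempts_per_probe):
            r = region.radius * np.sqrt(rng.random())
            theta = 2 * np.pi * rng.random()
            a = region.length * rng.random()
            center = (region.base_point + a * axis
                      + r * (np.cos(theta) * e1 + np.sin(theta) * e2))
            if not contains(region, center):
                continue
            rot = _quat_to_matrix(_random_quaternion(rng))
            coords = center + body @ rot.T
            heavy_coords = coords[heavy_local]
            if rec_pos.size and np.min(
                    np.linalg.norm(heavy_coords[:, None] - rec_pos[None], axis=-1)
            ) < min_separation:
                continue
            ok = True
            for other in placed_heavy:
                if np.min(np.linalg.norm(
                        heavy_coords[:, None] - other[None], axis=-1)) < min_separation:
                    ok = False
                    break
            if not ok:
                continue
            new_positions[group] = coords
            placed_heavy.append(heavy_coords)
            break
        else:
            raise RuntimeError(
                f"could not place probe after {max_attempts_per_probe} attempts; "
                "use fewer probes, a larger region, or a smaller min_separation")
    system.positions = new_positions
    return system


# ---------------------------------------------------------------------------
# Rigid-body Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass
class ProbeState:
    """Rigid-body state of one probe."""

    center: np.ndarray            # Å
    orientation: np.ndarray       # unit quaternion (x, y, z, w)
    velocity: np.ndarray          # Å/ps
    angular_velocity: np.ndarray  # rad/ps, body principal frame

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be normalized")


class _RigidProbe:
    """Precomputed per-probe rigid-body data in the principal frame."""

    def __init__(self, system: ParameterizedSystem, group: np.ndarray) -> None:
        self.group = group
        self.masses = np.array([system.atoms[i].mass for i in group])
        self.total_mass = float(self.masses.sum())
        pos = np.array([system.atoms[i].position for i in group])
        com = self.masses @ pos / self.total_mass
        body = pos - com
        # inertia tensor -> principal frame
        inertia = np.zeros((3, 3))
        for m, r in zip(self.masses, body):
            inertia += m * ((r @ r) * np.eye(3) - np.outer(r, r))
        evals, evecs = np.linalg.eigh(inertia)
        if np.linalg.det(evecs) < 0:
            evecs[:, -1] *= -1
        self.principal = np.maximum(evals, 0.0)       # amu Å²
        self.body_coords = body @ evecs               # coords in principal frame
        self.linear_only = bool(np.all(self.principal < 1e-10))
        self.rotatable = ~(self.principal < 1e-10)    # per-axis (linear molecules)
        self.init_center = com
        # initial orientation = principal axes (columns of evecs)
        self.init_rot = evecs


def _total_forces(probes: list[_RigidProbe], params, centers, rots, rec, model,
                  region, trap):
    """Nonbonded + wall (+ optional trap) forces; returns per-probe force,
    body-frame torque, and total potential energy."""
    n_p = len(probes)
    atom_pos = [centers[p] + probes[p].body_coords @ rots[p].T for p in range(n_p)]
    all_pos = np.concatenate(atom_pos) if n_p else np.zeros((0, 3))
    offsets = np.cumsum([0] + [len(p.group) for p in probes])

    f_atoms = np.zeros_like(all_pos)
    energy = 0.0
    q_all, e_all, r_all = params
    inert = not (np.any(q_all) or np.any(e_all))  # nothing to interact with
    if inert:
        rec = None
    if rec is not None and rec[0].size:
        e1, e2, f = nonbonded_energy(all_pos, q_all, e_all, r_all,
                                     rec[0], rec[1], rec[2], rec[3],
                                     model, forces=True)
        energy += e1 + e2
        f_atoms += f
    # probe-probe: loop over unordered pairs (few probes)
    for i in range(n_p if not inert else 0):
        for j in range(i + 1, n_p):
            si, sj = slice(offsets[i], offsets[i + 1]), slice(offsets[j], offsets[j + 1])
            e1, e2, fi, fj = nonbonded_energy(
                atom_pos[i], q_all[si], e_all[si], r_all[si],
                atom_pos[j], q_all[sj], e_all[sj], r_all[sj],
                model, forces="both")
            energy += e1 + e2
            f_atoms[si] += fi
            f_atoms[sj] += fj

    f_com = np.zeros((n_p, 3))
    tau_body = np.zeros((n_p, 3))
    for p in range(n_p):
        sl = slice(offsets[p], offsets[p + 1])
        f_com[p] = f_atoms[sl].sum(axis=0)
        arm = atom_pos[p] - centers[p]
        tau_lab = np.cross(arm, f_atoms[sl]).sum(axis=0)
        tau_body[p] = rots[p].T @ tau_lab

    if region is not None and region.k_wall > 0:
        ew, fw = wall_energy_force_batch(centers, region)
        energy += float(ew.sum())
        f_com += fw
    if trap is not None:
        k_t, c_t = trap
        disp = centers - np.asarray(c_t, float)
        energy += float(0.5 * k_t * (disp ** 2).sum())
        f_com += -k_t * disp
    return f_com, tau_body, energy


def run_langevin(system: ParameterizedSystem,
                 region: CylinderRegion | None,
                 config: RunConfig,
                 model: NonbondedModel | None = None,
                 trap: tuple[float, np.ndarray] | None = None) -> Trajectory:
    """Sample probe motion with rigid-body BAOAB Langevin dynamics.

    The receptor is held fixed; probes translate and rotate under nonbonded
    forces, the confinement wall (applied to each probe's center of mass)
    and, optionally, an external harmonic ``trap`` ``(k_t, center)`` used for
    physics validation.  Frames (full-system coordinates) are saved every
    ``config.save_interval`` steps, including the initial state.

    Identical ``(system, config)`` inputs with the same seed reproduce the
    trajectory bit-for-bit.  Raises :class:`RuntimeError` with the frame
    index if the potential energy diverges.
    """
    if model is None:
        model = NonbondedModel(cutoff=config.nonbonded_cutoff,
                               dielectric=config.dielectric)
    rng = np.random.default_rng(config.seed)
    probes = [_RigidProbe(system, g) for g in system.probes]
    if not probes:
        raise ValueError("system has no probes to sample")
    params = tuple(
        np.concatenate([np.array([getattr(system.atoms[i], attr) for i in p.group])
                        for p in probes])
        for attr in ("charge", "lj_epsilon", "lj_rmin_half"))

    rec_idx = system.receptor_indices
    rec = None
    if rec_idx.size:
        rec = (np.array([system.atoms[i].position for i in rec_idx]),
               np.array([system.atoms[i].charge for i in rec_idx]),
               np.array([system.atoms[i].lj_epsilon for i in rec_idx]),
               np.array([system.atoms[i].lj_rmin_half for i in rec_idx]))

    n_p = len(probes)
    h = config.dt_integration
    kbt = KB_KCAL * config.temperature * KCAL_TO_AKMA   # amu Å² ps⁻²
    gamma = config.friction
    c1 = np.exp(-gamma * h)
    c2 = np.sqrt(1.0 - c1 * c1)

    from scipy.spatial.transform import Rotation

    centers = np.array([p.init_center for p in probes])
    quats = [Rotation.from_matrix(p.init_rot).as_quat() for p in probes]
    rots = [_quat_to_matrix(q) for q in quats]
    masses = np.array([p.total_mass for p in probes])

    # Maxwell-Boltzmann initial velocities
    vel = rng.standard_normal((n_p, 3)) * np.sqrt(kbt / masses)[:, None]
    omega = np.zeros((n_p, 3))
    for p_i, p in enumerate(probes):
        sigma = np.where(p.rotatable, np.sqrt(kbt / np.maximum(p.principal, 1e-300)), 0.0)
        omega[p_i] = rng.standard_normal(3) * sigma

    def rotate_quats(dt_drift: float) -> None:
        # advance orientation by omega (body frame) over dt_drift:
        # q <- q ⊗ exp((0, ω · dt_drift / 2))
        for p_i, p in enumerate(probes):
            if p.linear_only:
                continue
            v = omega[p_i] * dt_drift / 2.0
            angle = np.linalg.norm(v)
            if angle < 1e-14:
                continue
            dq = np.empty(4)
            dq[:3] = np.sin(angle) * v / angle
            dq[3] = np.cos(angle)
            q = _quat_multiply(quats[p_i], dq)
            quats[p_i] = q / np.linalg.norm(q)
            rots[p_i] = _quat_to_matrix(quats[p_i])

    f_com, tau, energy = _total_forces(probes, params, centers, rots, rec,
                                       model, region, trap)
    if not np.isfinite(energy) or abs(energy) > config.energy_abort:
        raise RuntimeError(
            f"potential energy diverged ({energy:.3e} kcal/mol) at step 0 "
            "(initial configuration; check probe placement)")

    n_save = config.n_steps // config.save_interval + 1
    frames = np.empty((n_save, system.n_atoms, 3))
    base = system.positions
    ke_sum = 0.0

    def snapshot(slot: int) -> None:
        frame = base.copy()
        for p_i, p in enumerate(probes):
            frame[p.group] = centers[p_i] + p.body_coords @ rots[p_i].T
        frames[slot] = frame

    snapshot(0)
    saved = 1
    inv_m = 1.0 / masses[:, None]
    inv_inertia = np.array([np.where(p.rotatable, 1.0 / np.maximum(p.principal, 1e-300), 0.0)
                            for p in probes])
    sigma_v = np.sqrt(kbt / masses)[:, None]
    sigma_w = np.sqrt(kbt * inv_inertia)

    for step in range(1, config.n_steps + 1):
        # B
        vel += (0.5 * h * KCAL_TO_AKMA) * f_com * inv_m
        omega += (0.5 * h * KCAL_TO_AKMA) * tau * inv_inertia
        # A
        centers += 0.5 * h * vel
        rotate_quats(0.5 * h)
        # O
        vel = c1 * vel + c2 * sigma_v * rng.standard_normal((n_p, 3))
        omega = c1 * omega + c2 * sigma_w * rng.standard_normal((n_p, 3))
        # A
        centers += 0.5 * h * vel
        rotate_quats(0.5 * h)
        # B
        f_com, tau, energy = _total_forces(probes, params, centers, rots, rec,
                                           model, region, trap)
        if not np.isfinite(energy) or abs(energy) > config.energy_abort:
            raise RuntimeError(
                f"potential energy diverged ({energy:.3e} kcal/mol) at step "
                f"{step} (frame {saved - 1} was the last saved state)")
        vel += (0.5 * h * KCAL_TO_AKMA) * f_com * inv_m
        omega += (0.5 * h * KCAL_TO_AKMA) * tau * inv_inertia

        ke_sum += 0.5 * float((masses[:, None] * vel ** 2).sum())
        if step % config.save_interval == 0:
            snapshot(saved)
            saved += 1

    mean_ke_per_dof = ke_sum / (config.n_steps * 3 * n_p) / KCAL_TO_AKMA
    traj = Trajectory(
        system=system, frames=frames[:saved],
        dt=config.save_interval * h,
        metadata={
            "seed": config.seed,
            "temperature": config.temperature,
            "friction": config.friction,
            "n_steps": config.n_steps,
            "mean_kinetic_per_dof_kcal": mean_ke_per_dof,
            "final_potential_kcal": energy,
            "config": vars(config).copy(),
        })
    return traj
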