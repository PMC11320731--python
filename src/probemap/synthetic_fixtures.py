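"""Deterministic synthetic systems for testing the mapping workflow.

The toy receptor is a hollow spherical cage of single-atom residues with an
opening on a chosen face — a desk-scale stand-in for a seven-helix receptor
with an exposed intracellular pocket.  Residues ringing the opening are
annotated with the generic pocket labels used by the real protocol (anchors
2.43 / 7.56 / 8.48, hotspot positions 8.49 / 7.53 / 6.36), and one hotspot
residue can be made a planted attractor (extra Lennard-Jones well depth and
opposite partial charge) so recovery of known ground truth can be measured.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confinement import region_from_residues
from .core_io import (AtomRecord, BWMap, ParameterizedSystem, ProbeTemplate,
                      RunConfig, Trajectory, map_bw)
from .doseresponse import logistic4
from .probe_sampler import attach_probes, place_probes, run_langevin

__all__ = ["ToyReceptorSpec", "make_toy_receptor", "single_bead_probe",
           "planted_hotspot_trajectory", "simulate_dose_response",
           "ANCHOR_LABELS", "HOTSPOT_LABELS"]

ANCHOR_LABELS = ("2.43", "7.56", "8.48")
HOTSPOT_LABELS = ("8.49", "7.53", "6.36")


@dataclass
class ToyReceptorSpec:
    """Parameters of the toy cage receptor.

    ``attractor_strength`` (kcal/mol) is added to the planted hotspot
    residue's LJ well depth; a proportional negative partial charge
    (capped at −1 e) is planted alongside so both energy channels mark it.
    """

    n_shell_atoms: int = 180
    shell_radius: float = 12.0
    pocket_face: tuple[float, float, float] = (0.0, 0.0, -1.0)
    pocket_residues: int = 6
    attractor_strength: float = 2.0
    opening_half_angle: float = 35.0     # degrees
    jitter: float = 0.15                 # Å positional noise, seeded
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be > 0")
        if self.attractor_strength < 0:
            raise ValueError("attractor_strength must be >= 0")
        if self.pocket_residues > self.n_shell_atoms:
            raise ValueError("pocket_residues cannot exceed n_shell_atoms")
        face = np.asarray(self.pocket_face, float)
        n = np.linalg.norm(face)
        if n < 1e-12:
            raise ValueError("pocket_face must be a nonzero vector")
        self.pocket_face = tuple(face / n)


def _fibonacci_shell(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def make_toy_receptor(spec: ToyReceptorSpec
                      ) -> tuple[ParameterizedSystem, BWMap]:
    """Build the cage receptor and its pocket annotation.

    Shell atoms sit on a sphere of ``shell_radius`` with atoms inside a cone
    of ``opening_half_angle`` around ``pocket_face`` removed (the pocket
    mouth).  The ``pocket_residues`` atoms closest to the rim of the opening
    become the annotated pocket: the first three are the anchor positions
    2.43 / 7.56 / 8.48, the following ones the hotspot positions 8.49 /
    7.53 / 6.36 (cycled if more are requested).  The first hotspot residue
    (8.49) is the planted attractor.
    """
    face = np.asarray(spec.pocket_face, float)
    rng = np.random.default_rng(spec.seed)
    unit = _fibonacci_shell(spec.n_shell_atoms)
    cos_open = np.cos(np.radians(spec.opening_half_angle))
    keep = unit @ face < cos_open
    unit = unit[keep]
    pos = unit * spec.shell_radius
    pos = pos + rng.normal(scale=spec.jitter, size=pos.shape)

    # pocket residues: a compact patch on the opening rim — the atom nearest
    # the face plus its nearest neighbors, so anchors and hotspots are
    # mutually adjacent (as in a real pocket) rather than scattered
    scores = unit @ face
    seed_atom = int(np.argmax(scores))
    d_seed = np.linalg.norm(pos - pos[seed_atom], axis=1)
    pocket_idx = np.argsort(d_seed)[:spec.pocket_residues]

    labels = list(ANCHOR_LABELS) + list(HOTSPOT_LABELS)
    while len(labels) < spec.pocket_residues:
        labels.append(f"{len(labels)}.{90 + len(labels)}")
    # label in patch order: anchors on the three innermost atoms, the first
    # hotspot (the attractor) right next to them
    label_of = {int(idx): labels[rank]
                for rank, idx in enumerate(pocket_idx[:spec.pocket_residues])}

    atoms = []
    annotation = {}
    attractor_key = None
    for i in range(len(pos)):
        resid = i + 1
        resname = "SHL"
        charge = 0.0
        epsilon = 0.10
        if i in label_of:
            resname = "PKT"
            label = label_of[i]
            annotation[("A", resid)] = label
            if label == HOTSPOT_LABELS[0] and spec.attractor_strength > 0:
                resname = "ATT"
                epsilon += spec.attractor_strength
                charge = -min(1.0, 0.25 * spec.attractor_strength)
                attractor_key = ("A", resid)
        atoms.append(AtomRecord(
            serial=resid, name="CA", element="C", residue_name=resname,
            residue_id=resid, chain="A", position=pos[i], charge=charge,
            lj_epsilon=epsilon, lj_rmin_half=1.9, mass=12.011))
    system = ParameterizedSystem(atoms)
    bw = map_bw(system, annotation)
    system.metadata = {"attractor": attractor_key, "spec_seed": spec.seed}
    return system, bw


def single_bead_probe(charge: float = 0.3, epsilon: float = 0.15,
                      rmin_half: float = 1.9, mass: float = 40.0,
                      name: str = "bead") -> ProbeTemplate:
    """A one-atom probe: the simplest rigid body (no rotational DOF)."""
    return ProbeTemplate(
        name=name, atom_names=["C1"], elements=["C"],
        coords=np.zeros((1, 3)), charges=np.array([charge]),
        lj_epsilons=np.array([epsilon]), lj_rmin_halves=np.array([rmin_half]),
        masses=np.array([mass]))


def planted_hotspot_trajectory(spec: ToyReceptorSpec,
                               n_frames: int = 100,
                               seed: int = 0,
                               mode: str = "direct",
                               occupied_fraction: float = 0.6,
                               probe: ProbeTemplate | None = None,
                               n_probes: int = 4,
                               n_steps: int = 4000,
                               config: RunConfig | None = None):
    """A probe trajectory over the toy receptor with known ground truth.

    mode="direct"
        Frames are synthesized, not sampled: in an exact fraction
        ``occupied_fraction`` of frames (which frames is a seeded
        permutation) a single probe sits 3 Å outside the attractor residue;
        in the rest it sits far along the pocket axis (≥ 10 Å from every
        residue).  Analysis tests built on this mode are free of sampler
        stochasticity.
    mode="sampled"
        Runs the Langevin sampler inside a cylinder anchored on the
        2.43/7.56/8.48 residues.

    Returns ``(trajectory, ground_truth)`` where ground_truth records the
    attractor residue key, the annotation map and (direct mode) the planted
    occupied-frame flags.
    """
    if not 0.0 <= occupied_fraction <= 1.0:
        raise ValueError("occupied_fraction must lie in [0, 1]")
    system, bw = make_toy_receptor(spec)
    if probe is None:
        probe = single_bead_probe()
    anchors = [("A", bw.residue(lab)) for lab in ANCHOR_LABELS]
    region = region_from_residues(system, anchors, length=12.0)
    truth = {"attractor": system.metadata["attractor"], "bw_map": bw,
             "region": region}

    if mode == "direct":
        full = attach_probes(system, probe, 1)
        group = full.probes[0]
        attractor_key = system.metadata["attractor"]
        att_pos = np.array([full.atoms[i].position
                            for i in full.residue_atoms(attractor_key)]).mean(axis=0)
        # dwell point: between the attractor and its nearest anchor atom,
        # nudged outward, so the probe is inside the 4 A occupancy shell of
        # the pocket-center residues and the 5 A energy shell of the attractor
        anchor_atoms = np.concatenate(
            [full.residue_atoms(k, heavy_only=True) for k in anchors])
        anchor_pos = np.array([full.atoms[i].position for i in anchor_atoms])
        nearest = anchor_pos[np.argmin(np.linalg.norm(anchor_pos - att_pos, axis=1))]
        mid = 0.5 * (att_pos + nearest)
        near = mid + 1.5 * mid / np.linalg.norm(mid)
        far = region.base_point + region.axis * (spec.shell_radius + 25.0)

        n_occ = int(round(occupied_fraction * n_frames))
        flags = np.zeros(n_frames, dtype=bool)
        order = np.random.default_rng(seed).permutation(n_frames)
        flags[order[:n_occ]] = True
        base = full.positions
        frames = np.repeat(base[None], n_frames, axis=0)
        probe_body = base[group] - base[group].mean(axis=0)
        for f in range(n_frames):
            center = near if flags[f] else far
            frames[f, group] = center + probe_body
        traj = Trajectory(system=full, frames=frames, dt=1.0)
        truth["occupied_flags"] = flags
        truth["occupied_fraction"] = n_occ / n_frames
        return traj, truth

    if mode == "sampled":
        if config is None:
            config = RunConfig(seed=seed, n_steps=n_steps, save_interval=20,
                               n_probes=n_probes)
        full = attach_probes(system, probe, n_probes)
        place_probes(full, region, seed=seed,
                     min_separation=config.min_separation)
        traj = run_langevin(full, region, config)
        return traj, truth

    raise ValueError(f"unknown mode {mode!r}")


def simulate_dose_response(emax: float = 1.0,
                           log_ec50: float = -8.0,
                           hill: float = 1.0,
                           concentrations: np.ndarray | None = None,
                           n_replicates: int = 3,
                           noise_sd: float = 0.02,
                           seed: int = 0,
                           condition: str = "wt") -> pd.DataFrame:
    """Noisy 4PL data: response = 4PL(true) + N(0, noise_sd²), basal 0.

    Default design mirrors a typical agonist titration: 8 log-spaced
    concentrations from 10⁻¹¹ to 10⁻⁶·⁵ M, 3 replicates, σ = 0.02 response
    units.  Deterministic per seed.
    """
    for v in (emax, log_ec50, hill):
        if not np.isfinite(v):
            raise ValueError("true parameters must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if concentrations is None:
        concentrations = np.linspace(-11.0, -6.5, 8)
    concentrations = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        clean = logistic4(concentrations, emax, log_ec50, hill)
        noisy = clean + rng.normal(scale=noise_sd, size=clean.shape) \
            if noise_sd > 0 else clean
        for x, y in zip(concentrations, noisy):
            rows.append({"condition": condition, "replicate": rep,
                         "log10_conc": float(x), "response": float(y)})
    return pd.DataFrame(rows)
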