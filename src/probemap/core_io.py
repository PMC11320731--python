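"""Structures, parameters, trajectories and annotation tables.

Everything downstream (confinement, sampling, mapping analyses) works on the
containers defined here:

* :class:`AtomRecord` / :class:`ParameterizedSystem` — receptor + probe atoms
  with coordinates (Å), partial charges (e), Lennard-Jones parameters
  (kcal/mol, Å) and residue/chain bookkeeping.
* :class:`Trajectory` — ordered coordinate frames for one system.
* :class:`BWMap` — Ballesteros–Weinstein generic GPCR residue labels.
* :class:`RunConfig` — simulation/analysis settings with an explicit seed.

File formats are deliberately minimal and text-only: a PDB subset
(ATOM/HETATM/TER/END), XYZ trajectories with a time stamp on the comment
line, DCD read-only (via MDAnalysis), a whitespace probe-definition table and
a two/three-column CSV for residue annotations.  Units are Å, kcal/mol, amu,
ps and elementary charges throughout; residue numbering is 1-based as in PDB.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KB_KCAL",
    "AtomRecord",
    "ParameterizedSystem",
    "Trajectory",
    "BWMap",
    "RunConfig",
    "ProbeTemplate",
    "read_pdb",
    "write_pdb",
    "load_probe_definition",
    "packaged_probe_path",
    "map_bw",
    "read_bw_csv",
    "read_xyz",
    "write_xyz",
    "read_dcd",
    "VDW_RADII",
]

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: kcal/mol -> amu Å² ps^-2 (so that a = F * KCAL_TO_AKMA / m is in Å ps^-2).
KCAL_TO_AKMA = 418.4

#: Per-element van der Waals radii (Å) used for density rasterization,
#: pocket-volume grids and SASA.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}

_DEFAULT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974,
}

#: Elements classified as hydrophobic for SASA splitting (C and S; N, O, P
#: and polar hydrogens count as hydrophilic).
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})


@dataclass
class AtomRecord:
    """One atom with coordinates and (optionally) nonbonded parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    mass: float = 0.0
    is_probe: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be >= 0, got {self.lj_epsilon}")
        if self.mass == 0.0:
            self.mass = _DEFAULT_MASSES.get(self.element, 12.011)
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")

    @property
    def hydrophobic(self) -> bool:
        """True iff the element is apolar (C or S)."""
        return self.element in HYDROPHOBIC_ELEMENTS

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element, 1.7)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class ParameterizedSystem:
    """An ordered atom list plus residue and probe-group indices.

    Parameters
    ----------
    atoms:
        Ordered atom records. Every atom belongs to exactly one residue,
        keyed ``(chain, residue_id)``.
    probes:
        Disjoint groups of atom indices, one per probe molecule. Atoms in
        probe groups are flagged ``is_probe``.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 probes: Sequence[Sequence[int]] = ()) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        self.metadata: dict = {}
        self.probes: list[np.ndarray] = [np.asarray(g, dtype=int) for g in probes]
        seen: set[int] = set()
        for g in self.probes:
            gs = set(int(i) for i in g)
            if gs & seen:
                raise ValueError("probe groups must be disjoint")
            seen |= gs
            for i in gs:
                self.atoms[i].is_probe = True
        self._build_indices()

    def _build_indices(self) -> None:
        self.residues: dict[tuple[str, int], np.ndarray] = {}
        order: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            order.setdefault((a.chain, a.residue_id), []).append(i)
        self.residues = {k: np.asarray(v, dtype=int) for k, v in order.items()}
        self.residue_keys: list[tuple[str, int]] = list(self.residues)

    # -- array views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @positions.setter
    def positions(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_atoms, 3)}, got {value.shape}")
        for a, p in zip(self.atoms, value):
            a.position = p.copy()

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return self.array("charge")

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self.array("lj_epsilon")

    @property
    def lj_rmin_halves(self) -> np.ndarray:
        return self.array("lj_rmin_half")

    @property
    def masses(self) -> np.ndarray:
        return self.array("mass")

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def probe_mask(self) -> np.ndarray:
        m = np.zeros(self.n_atoms, dtype=bool)
        for g in self.probes:
            m[g] = True
        return m

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.nonzero(~self.probe_mask)[0]

    @property
    def probe_indices(self) -> np.ndarray:
        return np.nonzero(self.probe_mask)[0]

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def residue_atoms(self, key: tuple[str, int], heavy_only: bool = False) -> np.ndarray:
        if key not in self.residues:
            raise KeyError(f"unknown residue key {key!r}")
        idx = self.residues[key]
        if heavy_only:
            idx = idx[[self.atoms[i].is_heavy for i in idx]]
        return idx

    def copy(self) -> "ParameterizedSystem":
        atoms = [replace(a, position=a.position.copy()) for a in self.atoms]
        return ParameterizedSystem(atoms, [g.copy() for g in self.probes])


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_frames × n_atoms × 3, Å) for one system."""

    system: ParameterizedSystem
    frames: np.ndarray
    dt: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != system atom count "
                f"{self.system.n_atoms}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return "C"
    first = re.sub(r"[0-9]", "", stripped)
    if len(first) >= 2 and first[:2].capitalize() in _DEFAULT_MASSES:
        return first[:2].capitalize()
    return first[0].upper()


def read_pdb(path: str | Path) -> ParameterizedSystem:
    """Read ATOM/HETATM records from a PDB file (coordinates only).

    Nonbonded parameters are left unset; residue ids and chain identifiers
    are preserved verbatim.  Raises :class:`ValueError` naming the offending
    line on malformed coordinate fields, and on an empty file.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path.name}: malformed ATOM/HETATM record at line {lineno}: "
                    f"{exc}") from None
            element = line[76:78].strip().capitalize() or _guess_element(name)
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element, residue_name=resname,
                residue_id=resid, chain=chain, position=np.array([x, y, z])))
    if not atoms:
        raise ValueError(f"{path.name}: no ATOM/HETATM records found")
    return ParameterizedSystem(atoms)


def write_pdb(system: ParameterizedSystem, path: str | Path,
              positions: np.ndarray | None = None) -> None:
    """Write the system as ATOM records (TER between chains, END at the end)."""
    pos = system.positions if positions is None else np.asarray(positions, float)
    lines = []
    prev_chain = None
    for a, p in zip(system.atoms, pos):
        if prev_chain is not None and a.chain != prev_chain:
            lines.append("TER\n")
        prev_chain = a.chain
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
            f"{a.chain:1.1s}{a.residue_id:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}\n")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Probe templates
# ---------------------------------------------------------------------------

_PROBE_COLUMNS = ("name", "element", "x", "y", "z", "charge", "epsilon",
                  "rmin_half", "mass")


@dataclass
class ProbeTemplate:
    """A rigid probe molecule: atom names, body coordinates and parameters."""

    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray           # (n, 3) Å, arbitrary body frame
    charges: np.ndarray          # e
    lj_epsilons: np.ndarray      # kcal/mol
    lj_rmin_halves: np.ndarray   # Å
    masses: np.ndarray           # amu

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        self.coords = np.asarray(self.coords, float).reshape(n, 3)
        for attr in ("charges", "lj_epsilons", "lj_rmin_halves", "masses"):
            arr = np.asarray(getattr(self, attr), float)
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{attr} contains non-finite values")
            setattr(self, attr, arr)
        if np.any(self.lj_epsilons < 0):
            raise ValueError("epsilon must be >= 0 for every atom")
        if np.any(self.masses <= 0):
            raise ValueError("mass must be > 0 for every atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def centered_coords(self) -> np.ndarray:
        """Coordinates relative to the center of mass."""
        com = self.masses @ self.coords / self.total_mass
        return self.coords - com

    def to_atoms(self, residue_id: int, chain: str = "P",
                 residue_name: str = "PRB", serial_start: int = 1) -> list[AtomRecord]:
        return [AtomRecord(
            serial=serial_start + i, name=self.atom_names[i],
            element=self.elements[i], residue_name=residue_name,
            residue_id=residue_id, chain=chain, position=self.coords[i],
            charge=float(self.charges[i]), lj_epsilon=float(self.lj_epsilons[i]),
            lj_rmin_half=float(self.lj_rmin_halves[i]),
            mass=float(self.masses[i]), is_probe=True)
            for i in range(self.n_atoms)]


def load_probe_definition(path: str | Path) -> ProbeTemplate:
    """Load a rigid probe template from a whitespace-delimited table.

    Expected header: ``name element x y z charge epsilon rmin_half mass``.
    """
    path = Path(path)
    rows = []
    header: list[str] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split()
            missing = [c for c in _PROBE_COLUMNS if c not in header]
            if missing:
                raise ValueError(
                    f"{path.name}: probe table is missing column(s) {missing}")
            continue
        fields = line.split()
        if len(fields) != len(header):
            raise ValueError(
                f"{path.name}: line {lineno} has {len(fields)} fields, "
                f"expected {len(header)}")
        row = dict(zip(header, fields))
        try:
            numeric = {c: float(row[c]) for c in _PROBE_COLUMNS[2:]}
        except ValueError as exc:
            raise ValueError(f"{path.name}: line {lineno}: {exc}") from None
        if not all(math.isfinite(v) for v in numeric.values()):
            raise ValueError(f"{path.name}: line {lineno}: non-finite value")
        rows.append((row["name"], row["element"], numeric))
    if not rows:
        raise ValueError(f"{path.name}: no atom rows found")
    return ProbeTemplate(
        name=path.stem,
        atom_names=[r[0] for r in rows],
        elements=[r[1] for r in rows],
        coords=np.array([[r[2]["x"], r[2]["y"], r[2]["z"]] for r in rows]),
        charges=np.array([r[2]["charge"] for r in rows]),
        lj_epsilons=np.array([r[2]["epsilon"] for r in rows]),
        lj_rmin_halves=np.array([r[2]["rmin_half"] for r in rows]),
        masses=np.array([r[2]["mass"] for r in rows]))


def packaged_probe_path(name: str) -> Path:
    """Path to a packaged probe template: ``"nms"`` or ``"mmi"``."""
    p = Path(__file__).parent / "data" / f"{name.lower()}.probe"
    if not p.exists():
        raise FileNotFoundError(f"no packaged probe template named {name!r}")
    return p


# ---------------------------------------------------------------------------
# Ballesteros–Weinstein annotation
# ---------------------------------------------------------------------------

_BW_PATTERN = re.compile(r"^(\d+\.\d+|[A-Z]+\d*)$")


class BWMap:
    """Bijective map (chain, residue_id) <-> Ballesteros–Weinstein label.

    Labels are either helix.position strings such as ``"8.49"`` or named
    segments such as ``"IL1"``.  Lookups for unannotated residues return
    ``None`` explicitly rather than a default.
    """

    def __init__(self, table: Mapping[tuple[str, int], str]) -> None:
        self.forward: dict[tuple[str, int], str] = {}
        self.inverse: dict[tuple[str, str], int] = {}
        for (chain, resid), label in table.items():
            label = str(label).strip()
            if not _BW_PATTERN.match(label):
                raise ValueError(f"invalid Ballesteros–Weinstein label {label!r}")
            if (chain, label) in self.inverse:
                raise ValueError(
                    f"duplicate label {label!r} on chain {chain!r} "
                    f"(residues {self.inverse[(chain, label)]} and {resid})")
            self.forward[(chain, int(resid))] = label
            self.inverse[(chain, label)] = int(resid)

    def label(self, chain: str, residue_id: int) -> str | None:
        return self.forward.get((chain, residue_id))

    def residue(self, label: str, chain: str = "A") -> int | None:
        return self.inverse.get((chain, label))

    def __len__(self) -> int:
        return len(self.forward)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.forward


def map_bw(system: ParameterizedSystem,
           annotation: Iterable[tuple] | Mapping[tuple[str, int], str]) -> BWMap:
    """Build a :class:`BWMap` from annotation rows.

    ``annotation`` is either a mapping ``(chain, residue_id) -> label`` or an
    iterable of ``(residue_id, label)`` / ``(chain, residue_id, label)`` rows.
    Rows referring to residues absent from ``system`` are kept (annotation
    tables may cover the full-length receptor).
    """
    if isinstance(annotation, Mapping):
        table = dict(annotation)
    else:
        table = {}
        for row in annotation:
            if len(row) == 2:
                resid, label = row
                chain = "A"
            elif len(row) == 3:
                chain, resid, label = row
            else:
                raise ValueError(f"annotation row must have 2 or 3 fields: {row!r}")
            table[(str(chain), int(resid))] = str(label)
    return BWMap(table)


def read_bw_csv(path: str | Path) -> list[tuple]:
    """Read annotation rows from a CSV with columns (residue_id, label) or
    (chain, residue_id, label); a header line is skipped if present."""
    rows: list[tuple] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            if len(parts) == 2:
                rows.append((int(parts[0]), parts[1]))
            else:
                rows.append((parts[0], int(parts[1]), parts[2]))
        except ValueError:
            continue  # header line
    return rows


# ---------------------------------------------------------------------------
# Trajectory formats
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str | Path,
              elements: Sequence[str] | None = None) -> None:
    """Write an XYZ trajectory; the comment line records ``t= <ps> ps``."""
    if elements is None:
        elements = [a.element for a in traj.system.atoms]
    n = traj.frames.shape[1]
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"{n}\n")
            fh.write(f"t= {i * traj.dt:.6f} ps\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path: str | Path, system: ParameterizedSystem) -> Trajectory:
    """Read an XYZ trajectory written by :func:`write_xyz`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    times = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path.name}: expected atom count at line {i + 1}")
        comment = lines[i + 1]
        m = re.search(r"t=\s*([-+0-9.eE]+)", comment)
        times.append(float(m.group(1)) if m else float(len(times)))
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path.name}: truncated frame at line {i + 1}")
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    if not frames:
        raise ValueError(f"{path.name}: no frames found")
    dt = times[1] - times[0] if len(times) > 1 and times[1] > times[0] else 1.0
    return Trajectory(system=system, frames=np.asarray(frames), dt=dt)


def read_dcd(path: str | Path, system: ParameterizedSystem,
             topology_pdb: str | Path | None = None) -> Trajectory:
    """Read a DCD trajectory (read-only; frames must match the system)."""
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(str(path))
    frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
    dt = float(reader.ts.dt) if reader.ts.dt else 1.0
    reader.close()
    return Trajectory(system=system, frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Settings for sampling and analysis.  Every stochastic operation takes
    its randomness from ``seed``.

    Defaults mirror the mapping protocol: 310 K, 1.0 ps⁻¹ Langevin friction,
    12 Å nonbonded cutoff, 4 Å pocket-occupancy cutoff, 1 Å density grid
    analyzed at isovalue 0.5, 5 Å residue-energy shell, 3.5 Å / 90° hydrogen
    bonds.
    """

    temperature: float = 310.0      # K
    friction: float = 1.0           # ps^-1
    seed: int = 0
    n_steps: int = 50_000
    dt_integration: float = 0.002   # ps
    save_interval: int = 100        # steps between saved frames
    n_probes: int = 10
    min_separation: float = 2.5     # Å, initial placement
    nonbonded_cutoff: float = 12.0  # Å
    dielectric: float = 1.0
    occupancy_cutoff: float = 4.0   # Å
    density_spacing: float = 1.0    # Å
    density_isovalue: float = 0.5
    energy_shell: float = 5.0       # Å
    hbond_distance: float = 3.5     # Å
    hbond_angle: float = 90.0       # degrees
    contact_cutoff: float = 4.0     # Å
    k_wall: float = 10.0            # kcal mol^-1 Å^-2
    energy_abort: float = 1.0e6     # kcal/mol, divergence guard

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.dt_integration <= 0:
            raise ValueError("dt_integration must be > 0")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}\n" for k, v in vars(self).items()]
        Path(path).write_text("".join(lines))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: type(getattr(cls(), f.name))
                 for f in cls.__dataclass_fields__.values()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = types[key](value.strip())
        return cls(**kwargs)
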