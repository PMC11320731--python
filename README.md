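# probemap

Probe-confined dynamic mapping of receptor surface hotspots, at desk scale.

Cosolvent-style probe mapping asks a simple question of a receptor
structure: if small molecular fragments are allowed to wander near one
face of the protein, where do they stick? `probemap` implements the whole
loop needed to ask and answer it reproducibly:

* a **cylinder-shaped flat-bottom harmonic wall** that confines probes to
  the chosen face (open toward the receptor, closed elsewhere),
* a **rigid-body Langevin sampler** (BAOAB, 310 K, Coulomb +
  Lennard-Jones, fixed receptor) that makes the protocol executable
  without external MD software,
* the **trajectory statistics** that turn sampling into site predictions:
  pocket occupancy (% of frames with a probe within 4 Å of designated
  center residues), a 1 Å probe-density grid thresholded at isovalue 0.5,
  and per-residue electrostatic / van der Waals interaction-energy
  hotspot tables — plus hydrogen bonds (3.5 Å / 90°), contact
  frequencies (ionic-lock style), RMSF/RMSD, Shrake–Rupley SASA with a
  hydrophobic/hydrophilic split, and a grid cavity-volume estimate,
* the **validation-side statistics** used with cell-based assays:
  four-parameter logistic concentration–response fits with the basal
  fixed to zero, normalization to % of vehicle maximum, and the
  extra-sum-of-squares F test comparing shared vs independent fits,
* **synthetic fixtures** — toy receptors with planted attractive pockets
  annotated with generic (Ballesteros–Weinstein) labels, planted-truth
  trajectories, and noisy 4PL data — so every piece is testable offline.

The core model: probes feel U = U_Coulomb + U_LJ + U_wall, with
U_wall = ½k[max(0, r⊥−R)² + max(0, a−L)²] in cylinder coordinates, and a
residue is called a hotspot when its mean interaction energy
⟨E_elec⟩, ⟨E_vdW⟩ with a probe (over frames where the residue is within
5 Å of it) is strongly favorable.

Audience: method developers and structural bioinformaticians who want a
transparent, fully seeded implementation of the mapping protocol and its
statistics — not a production MD engine.

## Worked example

Sample probes over a toy receptor with a planted attractive pocket, then
recover the pocket with all three statistics:

```python
import probemap as pm
from probemap.core_io import RunConfig

spec = pm.ToyReceptorSpec(seed=1, attractor_strength=4.0)
cfg = RunConfig(seed=42, n_steps=10_000, save_interval=20, n_probes=6)
traj, truth = pm.planted_hotspot_trajectory(spec, seed=42, mode="sampled",
                                            n_probes=6, config=cfg)

occ = pm.pocket_occupancy(traj, bw_map=truth["bw_map"])
print(f"pocket occupancy: {occ.percent_frames_occupied:.1f}% of {traj.n_frames} frames")

table = pm.residue_interaction_energies(traj, bw_map=truth["bw_map"])
print(pm.rank_hotspots(table, key="total").head(3)
        [["residue_id", "bw", "elec_mean", "vdw_mean", "n_frames"]]
        .to_string(index=False))

grid = pm.density_grid(traj)
thr = pm.threshold_density(grid, isovalue=0.5)
print(f"density envelope: {thr.count} voxels at isovalue 0.5")
```

Output:

```
pocket occupancy: 93.6% of 501 frames
 residue_id   bw   elec_mean  vdw_mean  n_frames
        143 8.49 -103.059592 -0.087732       488
        148 None    0.000000 -0.122078       279
        101 None    0.000000 -0.108038        51
density envelope: 28 voxels at isovalue 0.5
```

All three readouts agree: the planted attractor (annotated 8.49, the
generic position of the primary anchoring residue in an intracellular
GPCR pocket) dominates the energy table by two orders of magnitude, the
pocket is occupied in ~94% of frames, and the suprathreshold density
envelope sits ~1.7 Å from the attractor. The dose–response side:

```python
ds = pm.simulate_dose_response(emax=1.0, log_ec50=-8.0, hill=1.0,
                               noise_sd=0.02, seed=3)
fit = pm.fit_4pl(ds)
print(f"emax={fit.emax:.3f}  logEC50={fit.log_ec50:.3f}  hill={fit.hill:.3f}")
# emax=0.985  logEC50=-8.010  hill=1.013
```

A command-line interface mirrors the library
(`probemap simulate|map|pocket|fit-dose|fixtures --help`).

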