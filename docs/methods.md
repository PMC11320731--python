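# Methods

## The mapping protocol

`probemap` implements a desk-scale version of probe-confined dynamic
mapping: small-molecule probes are restrained near one face of a receptor
by a cylinder-shaped flat-bottom harmonic wall, their motion is sampled
with Langevin dynamics, and binding-site hotspots are read out of the
trajectory with three complementary statistics — pocket occupancy, a
frame-averaged density grid, and per-residue interaction-energy
decomposition. A fourth, independent component implements the
concentration–response statistics (4PL fits, extra-sum-of-squares F test)
used to validate predicted residues in cell-based assays.

The package trades all-atom fidelity for complete testability: every
quantity it computes can be checked against a closed form, a brute-force
recomputation, a statistical-mechanics identity, or planted ground truth
in synthetic data. It is a toolkit for studying the *method*, not a
replacement for production MD.

## Confinement wall

The region is a cylinder with base point **b** (center of the open face,
on the receptor side), unit axis **n** pointing away from the receptor,
radius R and length L. For a point with axial coordinate
a = (**x** − **b**)·**n** and perpendicular distance r⊥,

    E(x) = ½ k [ max(0, r⊥ − R)² + max(0, a − L)² ]

with the axial term present only when the far end is closed. No penalty is
applied for a < 0: the face toward the receptor is open and the receptor
itself blocks escape. E is C¹ everywhere (both E and ∇E vanish at the
wall), rotation-invariant, and monotone along outward rays — all three are
property-tested. Default stiffness k = 10 kcal mol⁻¹ Å⁻² is a typical
flat-bottom restraint value; the cylinder is sized from the anchor
residues (radius = half the maximum anchor–anchor distance + 6 Å, length
15 Å) unless given explicitly. The wall acts on each probe's center of
mass and exerts no torque.

## Force field and units

Nonbonded interactions are Coulomb (k_c = 332.0637 kcal Å mol⁻¹ e⁻²,
uniform dielectric, default ε_r = 1) plus Lennard-Jones in Rmin form with
Lorentz–Berthelot-style combination (geometric-mean well depth, additive
half-radii). Pairs beyond the 12 Å cutoff are excluded; an optional
CHARMM-style switching function takes energy and force smoothly to zero.
Units are Å, ps, amu, kcal/mol and elementary charges throughout
(1 kcal/mol = 418.4 amu Å² ps⁻²; k_B = 0.0019872041 kcal mol⁻¹ K⁻¹).
Solvent and membrane are implicit in the dielectric and the friction
coefficient; there are no periodic boundaries and no explicit water.

Receptor and probe parameters are supplied per atom in definition files.
The packaged NMS (N-methylthiophene-2-sulfonamide) and MMI
(4-methoxy-1-methylindazole) templates carry placeholder Gasteiger
charges and generic per-element LJ parameters; both are meant to be
overridden when better parameters are available.

## Sampler

Probes are rigid bodies; the receptor is fully fixed (a simplification of
restraining backbone atoms — side-chain response is deliberately given
up). The integrator is a BAOAB splitting at 310 K with friction 1.0 ps⁻¹
and a 2 fs (0.002 ps) time step: half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick. Rotations use
unit quaternions advanced with the body-frame angular velocity about the
principal axes of each probe's inertia tensor; the inertial (Euler)
coupling term ω × Iω is dropped, a standard simplification for
thermostatted rigid-body sampling at moderate friction. Single-bead
probes skip rotation. One seeded PCG64 generator drives initial
velocities, placement and the O-step noise; identical (system, config,
seed) inputs reproduce trajectories bit-for-bit, and every run records
its resolved configuration in the trajectory metadata.

Validated identities: positional variance k_BT/k in a harmonic trap and
kinetic energy ½k_BT per translational degree of freedom (both within 5%
at 2×10⁵ steps — the trap test pools the three equivalent axes of the
isotropic trap, since a per-axis estimate at that length carries ~4%
statistical noise of its own, and uses near-critical damping for fastest
decorrelation), the Einstein free-diffusion slope 6k_BT/(mγ) within 10%
(time-origin-averaged MSD over 40 non-interacting beads), and wall
containment (<1% of saved frames more than 1 Å outside the region).

A divergence guard aborts with the offending step index when |E| exceeds
a configurable threshold (10⁶ kcal/mol by default), including at the
initial configuration — a probe started inside an LJ core would otherwise
be ejected at enormous velocity before the first in-loop check.

## Trajectory statistics

* **Occupancy** — a frame counts as occupied when any probe heavy atom is
  within 4 Å of any heavy atom of any pocket-center residue (the union
  over centers, defaulting to generic positions 2.43, 7.56 and 8.48);
  reported as % of frames. Any-heavy-atom, not center-of-mass, is the
  implemented convention.
* **Density grid** — per frame a voxel (1 Å cell side) is occupied when
  its center falls inside the van der Waals sphere of a selected atom
  (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2, P 1.8 Å); the grid value is the
  occupied-frame fraction, thresholded at isovalue 0.5 with the rule
  value ≥ isovalue *and* value > 0 (so isovalue 0 still excludes
  never-visited voxels). Export as OpenDX or pseudo-atom PDB.
* **Hotspot table** — residues with any heavy atom within 5 Å of a probe
  in a frame contribute their full residue–probe electrostatic and vdW
  energy; means ± SD are taken over *contributing* frames (averaging
  zeros over all frames would dilute hotspots; `average_over="all"` is
  available). With an infinite shell the decomposition adds up exactly to
  the whole receptor–probe pair energy frame by frame. Ranking is
  ascending by mean energy (most favorable first), ties broken by residue
  id.
* **Hydrogen bonds** — donor–acceptor distance ≤ 3.5 Å and D–H···A angle
  ≥ 90°. The 90° convention is ambiguous in the field; here it is the
  *minimum angle at the hydrogen* (180° = linear), so an 85° approach at
  2.8 Å is rejected.
* **Contacts** — fraction of frames with minimum heavy-atom distance
  ≤ 4 Å between two groups (e.g. the 3.49–3.50 ionic-lock pair).
* **RMSF/RMSD** — Kabsch superposition (proper rotations only, det = +1)
  onto the mean structure (two alignment passes) or a reference frame;
  RMSF is reported per atom or averaged per residue over heavy atoms.

## Pocket geometry

SASA is Shrake–Rupley with a Fibonacci point lattice (default 960 points,
probe 1.4 Å); areas split into hydrophobic (C, S) and hydrophilic
(everything else) contributions that sum exactly to the total. The
element-based partition rule is a declared convention — the field has no
single standard.

Cavity volume is a transparent grid estimate, not alpha-sphere pocket
detection: voxels inside the confinement region count when a water-sized
probe centered there clears every atom (surface gap ≥ 1.4 Å) while
remaining within reach of the receptor surface (gap ≤ 2·probe_radius +
the largest vdW radius present ≈ 4.6 Å, which excludes open solvent).
The adjacency bound is a design choice: a strict "2 probe radii from the
surface" rule would hollow out the middle of cavities wider than ~6 Å,
which is exactly the scale of interest. On a constructed cubic cage with
a 10×10×10 Å accessible interior the estimator reads ≈940 Å³ (6% low,
from corner rounding) and is stable to halving the grid spacing.

## Dose–response statistics

The model is the four-parameter logistic in log10-concentration form,

    y = basal + (emax − basal) / (1 + 10^((logEC50 − x)·h)),

fitted by unweighted least squares with basal fixed to 0 (the ΔEbBRET
convention: agonist minus vehicle is zero without agonist). Initialization
is a deterministic profiled grid: for each (logEC50, hill) on a grid
spanning the observed concentration range with h ∈ {±0.5, ±1, ±2}, emax
is solved linearly; the best grid point seeds a Levenberg–Marquardt
refine. Negative hill values admit inhibition-style (descending) curves.
Standard errors come from the Jacobian at the optimum; flat data are
flagged ill-conditioned rather than silently returned.

Condition comparisons use the extra-sum-of-squares F test between
independent per-condition fits and a global fit sharing one parameter
(emax, logEC50 or hill — both are exposed because which parameter a given
comparison shares is a per-experiment choice):

    F = ((SS_sh − SS_ind)/(df_sh − df_ind)) / (SS_ind/df_ind).

Calibration is verified by simulation: with the shared parameter truly
equal, the test rejects at α = 0.05 in 3–7% of 1000 simulated dataset
pairs. Responses can be normalized to % of the vehicle condition's
maximum observed response (its maximum maps to 100%).

## Synthetic fixtures

The toy receptor is a hollow spherical cage of single-atom residues
(default 180 lattice points, radius 12 Å, ~0.15 Å seeded jitter) with a
35° cone opening on a chosen face. The pocket is a *compact patch* on the
opening rim — the atom nearest the face plus its nearest neighbors — so
that the annotated anchors (2.43/7.56/8.48) and hotspots (8.49/7.53/6.36)
are mutually adjacent, as in a real pocket; scattering them around the rim
would decouple the planted attractor from the occupancy centers. The
first hotspot residue (8.49) is the planted attractor: its LJ well depth
is deepened by `attractor_strength` (default 2 kcal/mol) and it carries a
proportional negative charge, so both energy channels mark it.

Trajectory fixtures come in two modes. *Direct* mode synthesizes frames
with a probe dwelling at the pocket in an exact prescribed fraction of
frames (a seeded permutation chooses which), so analysis tests carry no
sampler stochasticity. *Sampled* mode runs the real sampler in a cylinder
anchored on the annotated pocket. What passing tests show: the analysis
chain recovers planted ground truth (top-1 hotspot recovery in ≥9/10
sampling seeds; occupancy far higher with the attractor than without).
What they do not show: anything about force-field accuracy, receptor
flexibility, membrane effects, or real chemokine-receptor geometry — the
cage has no helices, no backbone, and single-atom residues.

Dose–response fixtures add Gaussian noise (default σ = 0.02 response
units, 3 replicates at 8 log-spaced concentrations from 10⁻¹¹ to
10⁻⁶·⁵ M) to an exact 4PL curve.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use: 2×10⁵ integrator steps
for the trap identities, 5×10⁴ steps × 10 probes for containment,
10 sampling seeds × 5×10³ steps for hotspot recovery, 50–200-frame
fixtures for the analysis oracles, 100 noisy fits for EC50 recovery and
1000 dataset pairs for F-test calibration — sizes chosen so the whole
suite completes in minutes on one core while every statistical band
retains comfortable margin. Degenerate inputs (empty selections, single
frames, overlapping atoms, donors without hydrogens, all-zero reference
conditions) raise informative errors rather than returning defaults.

## Known limitations

* Fixed receptor, rigid probes, implicit solvent: no induced fit, no
  desolvation physics, no competing water.
* Plain cutoff electrostatics by default (switching optional); no Ewald.
* The toy receptor's single-atom residues make "residue energies" and
  "heavy atoms" coincide; real PDB inputs exercise the multi-atom paths,
  which are covered by the handwritten-fixture tests.
* Hotspot SD is over contributing frames only; comparing residues with
  very different contact frequencies should use `n_frames` alongside the
  means.
* The pocket-volume estimator depends on the confinement region and the
  adjacency bound; it is a comparative, not an absolute, cavity measure.
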