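# Methods

## The supervision model

SuMD treats binding-pathway sampling as a sequence of short unbiased MD
windows filtered by a distance criterion. The supervised variable is the
Euclidean distance between the ligand centre of mass and the mass-weighted
centroid of a fixed set of binding-site residues. Within each window the
distance samples are fitted by ordinary least squares; the window is kept
iff the fitted slope is strictly negative, with two deliberate tie-breaks:

- a slope of exactly zero **rejects** — a flat window makes no progress, and
  the acceptance rule is strict negativity;
- a window whose *final* sampled distance is below the hand-off threshold is
  classified **bound** regardless of its slope — the stop rule is on
  distance, not trend, and discarding a window that achieved the goal would
  be perverse.

On rejection the pre-window positions *and clock* are restored bit-exactly
and only velocities are redrawn (Maxwell–Boltzmann at the thermostat
temperature). Restoring the clock means "supervised time" counts accepted
windows only; `total_attempted_time` additionally counts rejected windows.
No memory of previously visited regions is kept: the tabu-like character
lives entirely in the accept/reject rule.

Because acceptance conditions only on the sign of a noisy slope, the
sequence of window-final distances is *not* monotone, and must not be — the
scheme filters drift, not fluctuations. Termination is guaranteed by two
safeguard caps (consecutive-failure cap, default 40; total-window cap,
default 500); both are package conventions, chosen large enough never to
fire in routine runs.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| window_length | 200 (ion preset) / 600 (small molecule) | ps | shorter windows suit fast-diffusing species |
| distance_sample_interval | window/10 | ps | 10 fitted points per window; must be a multiple of the frame stride |
| threshold | 5 | Å | hand-off to plain MD once inside the site |
| max_consecutive_failures | 40 | – | safeguard; termination guarantee |
| max_total_windows | 500 | – | safeguard; termination guarantee |

## The engine

A minimal NVT Langevin integrator using the BAOAB splitting at dt = 2 fs,
temperature 310 K, with frames saved every 20 ps. BAOAB reduces exactly to
velocity Verlet when friction and temperature are zero, which is how the
energy-conservation check is run. The ligand (1–5 beads) is integrated as a
single rigid *translating* body: forces are summed over beads and applied to
the centre of mass; rotational and internal degrees of freedom are not
integrated. Box walls reflect (no periodic imaging): minimum-image
bookkeeping would add complexity irrelevant to the supervision logic.

Thermostat noise is pre-generated from a numpy PCG64 generator whose state
is carried inside `SimState`, making segments bitwise reproducible and
exactly continuable; velocity-randomisation draws on restarts use a separate
stream spawned from the run seed, so the accept/reject sequence cannot
perturb the dynamics noise and vice versa.

### Friction

The engine default is 1 ps⁻¹ — the conventional *thermostat damping* for
simulations whose friction really comes from explicit solvent. The toy
model has no solvent, so for binding experiments the Langevin friction
itself must supply solvent drag: the reference experiments use γ = 50 ps⁻¹,
which for the 23 amu ligand gives D = kT/(mγ) ≈ 0.2 Å²/ps, the physical
ballpark for a solvated monatomic cation. At γ = 1 the toy ligand diffuses
two orders of magnitude too fast, window endpoints decorrelate from their
starts, and the distance-slope signal degenerates.

## The synthetic system

`build_receptor_model` constructs the reference funnel system (all geometry
is invented plumbing — there is no reduced reference model to copy):

- an **orthosteric** Gaussian well (8 kcal/mol, width 2.5 Å) at the bottom
  of a funnel of soft-sphere beads (ε = 1 kcal/mol, σ = 2.5 Å, repulsion
  clamped at 10³ kcal/mol), ringed by four marker beads whose centroid
  defines the site centre exactly;
- a **meta-binding** well (3 kcal/mol) on the funnel rim — a solvent-exposed
  decoy the ligand can station at en route, emulating a vestibular
  metastable site;
- an **allosteric** well (4.8 kcal/mol) below the pocket behind a bead-lined
  channel, emulating a buried ion pocket;
- an 80 Å reflecting box with the ligand started 43 Å from the pocket.

The box size was chosen so that *unsupervised* binding within the 10 ns
reference budget is a rare event (~10% of seeds), the regime the method
addresses; in a 60 Å box plain MD binds too often for the toy to be an
interesting benchmark, although supervision accelerates binding there too.
The `funnel_scale` switch widens the funnel-mouth and pocket-wall radii to
emulate the extra flexibility of an opened-up extracellular vestibule;
receptor beads are otherwise frozen so the supervision loop remains the
object under test.

What the toy does **not** emulate: explicit solvent and its kinetic effects
beyond Stokes drag, receptor conformational dynamics, ligand internal
degrees of freedom, electrostatics beyond an optional uniform-dielectric
Coulomb term, and all-atom energetics. Passing tests therefore demonstrate
the correctness of the supervision/analysis machinery and the qualitative
physics of funnel binding — not force-field-level realism.

## Reference binding experiment

Twenty paired seeds; for each, one supervised run (200 ps windows, 5 Å
threshold, 50-window budget = 10 ns attempted) and one plain-MD run of the
same attempted duration on the same system. Scored by (a) the number of
runs reaching the bound state in-budget, compared by a one-sided sign test
on discordant pairs, and (b) mean first-binding time, with unbound runs
censored at the budget — censoring *understates* the supervised advantage,
since the true unsupervised binding time exceeds the budget. Problem sizes
(20 seeds, 10 ns budget) keep the full experiment around a minute on one
CPU.

## Analysis stack

- **Kabsch superposition** via the SVD-based optimal rotation
  (scipy's `align_vectors`), always proper (det +1); degenerate (collinear)
  point sets are rejected rather than silently resolved.
- **RMSD series**: each frame is superposed on the reference over the fit
  selection (receptor), RMSD reported over the measure selection (ligand),
  plus the series minimum — the usual crystal-pose comparison.
- **Pairwise RMSD matrix** between frames is computed *without*
  re-superposition: positions are already in the receptor frame, and the
  point of clustering is to map where the ligand stations in that frame.
  For a single-particle ligand this is the Euclidean distance matrix.
- **DBSCAN** (scikit-learn) with defaults eps = 1.5 Å, min_samples = 5 —
  both exposed, since no canonical values exist for this use. Cluster
  centroids are unweighted means of member positions. Tests check the
  labelling against a literal density-reachability implementation; border
  points shared by two clusters are the only legitimate divergence.
- **Pocket volume**: cubic lattice (default 1.0 Å; 0.5 Å in oracle checks)
  over a spherical inclusion region (default radius 9 Å); points inside the
  sphere and outside every atom's vdW + padding sphere are counted, times
  the cell volume. Padding default 1.09 Å (hydrogen-probe allowance); vdW
  radii from a built-in Bondi table, overridable per atom via the B-factor
  column of generated PDB files. The volume is monotone non-increasing in
  occluders and padding and bounded by (4/3)πr³. When comparing compact vs
  widened toy pockets the inclusion sphere must sit *inside* the pocket
  walls (6 Å for the toy), otherwise the measurement probes bulk solvent.
- **Contacts**: a residue contacts the ligand in a frame iff any atom pair
  is within the cutoff (default 4.5 Å, heavy-atom convention); frequencies
  are contact frames over total frames, order-invariant.
- **Energies**: the toy non-bonded decomposition returns (Coulomb,
  wells+repulsion) whose sum equals the total potential exactly.

## Numerical conventions

Units: Å, ps, amu, kcal/mol, K; k_B = 0.0019872041 kcal/(mol·K); Coulomb
constant 332.0636 kcal·Å/(mol·e²); 1 kcal/mol = 418.4 amu·Å²/ps². The
clamped repulsion has zero force on its plateau (the energy is constant
there), so forces remain finite everywhere including bead centres. XYZ
coordinates round-trip exactly at 3 decimals; generated PDB files store
bead mass in the occupancy column and vdW radius in the B-factor column so
coarse-grained pseudo-atoms survive a round-trip.

## Known limitations

- The engine integrates a single rigid translating ligand; flexible or
  rotating multi-bead ligands are out of scope.
- DCD output is not implemented (XYZ plus a JSON frame sidecar covers the
  toolkit's needs); mmCIF and topology formats are likewise out of scope.
- Crystal-structure verification targets (ion-coordination counts, pocket
  volumes of prepared receptor structures) require externally supplied PDB
  files; the shipped fixture for that code path is an idealised synthetic
  sodium site, clearly labelled as such.
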