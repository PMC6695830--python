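# sumdkit

Supervised molecular dynamics (SuMD) is a tabu-like sampling scheme for
ligand–receptor **binding pathways**: instead of waiting hundreds of
nanoseconds for a ligand to find its site by free diffusion, short windows of
*unbiased* MD are run, the ligand-to-site distance is monitored, and only
windows in which the ligand approaches the site are kept — the rest are
re-run from the same configuration with freshly randomised velocities. No
biasing force ever acts on the system, so every kept frame is a physically
valid configuration, yet complete binding events are sampled in a few
nanoseconds of "supervised" time.

`sumdkit` implements the SuMD control loop against a minimal engine
contract, ships a self-contained coarse-grained Langevin receptor–ligand
system to exercise it on a single CPU, and provides the trajectory-analysis
stack used to characterise binding pathways: Kabsch superposition and RMSD
series, pairwise-RMSD matrices with DBSCAN clustering of ligand/ion
positions, POVME-style grid-based pocket volume, per-residue contact
frequencies, and interaction-energy decomposition.

## The algorithm

Let **c** be the mass-weighted centroid of the binding-site residues and
d(t) the distance from the ligand centre of mass to **c**. Dynamics is run
in windows of length Δt (presets: 200 ps for ions, 600 ps for small
molecules). Within each window, d is sampled at regular intervals and fitted
by ordinary least squares,

    d(t) ≈ a + m·t ,   m = Σ(tᵢ−t̄)(dᵢ−d̄) / Σ(tᵢ−t̄)² ,

and the window is

- **bound** if the final sampled distance is below the hand-off threshold
  (5 Å by default) — supervision is disabled and plain MD continues;
- **accepted** if m < 0 (the ligand is approaching): the run continues from
  the window's end state;
- **rejected** otherwise: positions and clock are restored to the window
  start and velocities are redrawn from the Maxwell–Boltzmann distribution
  at the thermostat temperature.

The engine behind the loop is an NVT Langevin integrator (BAOAB splitting,
2 fs step, 310 K, reflecting box walls); any engine that can advance a
state, expose it including its RNG, and redraw thermal velocities satisfies
the same contract.

The built-in test system is a bead-model receptor: a funnel of repulsive
beads leads to an orthosteric Gaussian well (8 kcal/mol, the global
minimum), a shallower meta-binding well (3 kcal/mol) sits on the funnel rim
as a solvent-exposed decoy, and a bead-lined channel below the pocket opens
onto an allosteric well — the topology of a GPCR-like binding problem in a
form cheap enough for property-based testing.

## Worked example

```bash
sumdkit generate-system --seed 1 --out-prefix sys
# -> wrote sys.pdb (51 atoms)          # 50 receptor beads + 1 ligand bead

sumdkit run-sumd --friction 50 --seed 7 --window-ps 200 --threshold-a 5 \
                 --post-ps 400 --out-dir run
# -> {"termination": "bound", "supervised_time_ps": 800.0,
#     "total_attempted_time_ps": 1600.0, "first_binding_time_ps": 700.0,
#     "n_accepted": 4, "n_rejected": 4}
```

The ligand started 43 Å from the pocket and reached it (distance < 5 Å)
after 800 ps of accepted ("SuMD") time out of 1.6 ns attempted; four windows
were discarded and re-run. `--friction 50` selects solvent-like Langevin
damping for the bare bead model (see `docs/methods.md`). The run directory
contains the accepted trajectory (`trajectory.xyz`), a per-window log
(`windows.tsv`: index, slope, accepted flag, final distance), `summary.json`
and a reproducibility manifest.

```bash
sumdkit analyze cluster --traj run/trajectory.xyz --topology sys.pdb --eps 2.0
# -> {"n_clusters": 1, "n_noise": 34,
#     "centroids": [[40.15, 39.88, 27.19]]}
```

DBSCAN on the pairwise-RMSD matrix of ligand positions finds one dense
population whose centroid (40.2, 39.9, 27.2) is the orthosteric pocket
(40, 40, 26.7) — the bound state; the 34 noise frames are the approach path.

```bash
sumdkit analyze contacts --topology sys.pdb --traj run/trajectory.xyz
# -> {"top_contacts": [[1, 0.45], [4, 0.43], [2, 0.40], ...]}

sumdkit analyze volume --topology sys.pdb --traj run/trajectory.xyz \
                       --center 40,40,26.667 --radius-a 6 --spacing-a 0.5
# -> {"mean_volume_A3": 14.78}
```

The most contacted residues (1–4) are exactly the beads lining the
orthosteric pocket, and the grid-based pocket volume tracks how much of the
6 Å inclusion sphere is free of (padded) receptor atoms per frame.

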