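"""Analysis stack vs independent oracles (brute force / Monte Carlo /
numerical optimisation)."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from sumdkit import (
    PotentialSpec,
    Trajectory,
    Well,
    build_receptor_model,
    contact_frequencies,
    coordination_number,
    dbscan,
    kabsch_superpose,
    nonbonded_energy,
    pairwise_rmsd_matrix,
    pocket_volume,
    potential_energy,
    rmsd_series,
    select_atoms,
    volume_series,
)
from sumdkit.analysis import plot_contact_polar
from sumdkit.errors import GeometryError, ParameterError, SelectionError
from sumdkit.model import AtomRecord


def atom(serial, resid, pos, name="X", chain="A", vdw=1.7):
    return AtomRecord(serial=serial, name=name, residue_name="RES",
                      residue_id=resid, chain=chain,
                      position=np.asarray(pos, float), mass=12.0, vdw_radius=vdw)


def static_traj(coords_per_frame, topology, dt=20.0):
    coords = np.asarray(coords_per_frame, dtype=float)
    times = dt * np.arange(1, coords.shape[0] + 1)
    return Trajectory(times=times, coords=coords, topology=topology, stride=dt)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


class TestKabsch:
    def test_identity_on_itself(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd < 1e-8

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(8, 3))
        mobile = ref.copy()
        mobile[:, 0] *= -1  # reflection: best proper rotation still det=+1
        rot, _, _ = kabsch_superpose(mobile, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_brute_force(self):
        """Optimal RMSD equals a direct numerical minimisation over
        quaternion-parameterised rotations (within 1e-6)."""
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3))
        true_rot = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        mobile = ref @ true_rot.T + rng.normal(0.0, 0.1, size=(10, 3)) + [1.0, 2.0, 3.0]
        _, _, rmsd = kabsch_superpose(mobile, ref)

        mob_c = mobile - mobile.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)

        def objective(q):
            q = q / np.linalg.norm(q)
            moved = mob_c @ Rotation.from_quat(q).as_matrix().T
            return np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1)))

        best = min(
            (
                minimize(objective, q0, method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}).fun
                for q0 in np.random.default_rng(4).normal(size=(8, 4))
            )
        )
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def _system(self):
        topo = [atom(1, 1, [0, 0, 0], chain="R"), atom(2, 1, [4, 0, 0], chain="R"),
                atom(3, 2, [0, 4, 0], chain="R"), atom(4, 3, [2, 2, 5], chain="L")]
        ref = np.array([a.position for a in topo])
        return topo, ref

    def test_self_trajectory_is_zero(self):
        topo, ref = self._system()
        traj = static_traj([ref, ref, ref], topo)
        series = rmsd_series(traj, ref, np.arange(3), np.array([3]))
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_translated_ligand_reads_exactly(self):
        topo, ref = self._system()
        moved = ref.copy()
        moved[3] += [0.0, 0.0, 1.0]  # ligand shifted 1 A, receptor fixed
        traj = static_traj([moved], topo)
        series = rmsd_series(traj, ref, np.arange(3), np.array([3]))
        assert series.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_min_is_a_lower_bound(self):
        rng = np.random.default_rng(5)
        topo, ref = self._system()
        frames = ref + rng.normal(0, 0.5, size=(6, 4, 3))
        traj = static_traj(frames, topo)
        series = rmsd_series(traj, ref, np.arange(3), np.array([3]))
        assert np.all(series.rmsd_min <= series.values + 1e-15)
        assert series.values[series.argmin_frame] == series.rmsd_min


# ---------------------------------------------------------------------------
# pairwise RMSD + DBSCAN
# ---------------------------------------------------------------------------


class TestPairwiseRmsd:
    def test_two_frames_at_known_distance(self):
        pts = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert np.allclose(pairwise_rmsd_matrix(pts), [[0, 3], [3, 0]])

    def test_symmetric_zero_diagonal(self):
        pts = np.random.default_rng(6).normal(size=(15, 3))
        m = pairwise_rmsd_matrix(pts)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)

    def test_multi_atom_brute_force(self):
        """Entries equal the double-loop coordinate RMSD."""
        frames = np.random.default_rng(7).normal(size=(10, 4, 3))
        m = pairwise_rmsd_matrix(frames)
        for i in range(10):
            for j in range(10):
                expected = np.sqrt(np.mean(np.sum((frames[i] - frames[j]) ** 2, axis=1)))
                assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_rmsd_matrix(np.zeros((0, 3)))


def dbscan_oracle(points, eps, min_samples):
    """Literal density-reachability DBSCAN, O(n^2)."""
    pts = np.asarray(points)
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    neighbours = [np.nonzero(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbours])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbours[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    return labels


def labels_equivalent(a, b):
    """Equality up to a permutation of cluster ids (noise fixed at -1)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or np.any((a == -1) != (b == -1)):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestDbscan:
    def test_two_blobs(self):
        rng = np.random.default_rng(8)
        pts = np.concatenate([
            rng.normal([0, 0, 0], 0.5, size=(100, 3)),
            rng.normal([20, 0, 0], 0.5, size=(100, 3)),
        ])
        res = dbscan(pts, eps=2.0, min_samples=5)
        assert res.n_clusters == 2
        assert np.all(res.labels >= 0)
        assert labels_equivalent(res.labels, dbscan_oracle(pts, 2.0, 5))
        # centroids sit at the blob centers
        cx = np.sort(res.cluster_centroids[:, 0])
        assert np.allclose(cx, [0.0, 20.0], atol=0.5)

    def test_single_point_min_samples_one(self):
        res = dbscan(np.zeros((1, 3)), eps=1.0, min_samples=1)
        assert res.n_clusters == 1 and res.labels[0] == 0

    def test_sparse_points_all_noise(self):
        pts = 100.0 * np.arange(10)[:, None] * np.array([[1.0, 0.0, 0.0]])
        res = dbscan(pts, eps=0.5, min_samples=2)
        assert res.n_clusters == 0 and np.all(res.labels == -1)

    def test_order_invariance_up_to_relabelling(self):
        rng = np.random.default_rng(9)
        pts = np.concatenate([
            rng.normal([0, 0, 0], 0.4, size=(50, 3)),
            rng.normal([10, 0, 0], 0.4, size=(50, 3)),
        ])
        perm = rng.permutation(len(pts))
        res = dbscan(pts, eps=1.5, min_samples=4)
        res_p = dbscan(pts[perm], eps=1.5, min_samples=4)
        assert labels_equivalent(res.labels[perm], res_p.labels)

    def test_matches_oracle_on_mixed_instances(self):
        """Random 200-point instances across several (eps, min_samples)."""
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            pts = np.concatenate([
                rng.normal([0, 0, 0], 1.0, size=(80, 3)),
                rng.normal([8, 0, 0], 1.0, size=(80, 3)),
                rng.uniform(-20, 20, size=(40, 3)),
            ])
            for eps, ms in [(1.5, 5), (2.5, 10), (1.0, 3)]:
                got = dbscan(pts, eps=eps, min_samples=ms).labels
                want = dbscan_oracle(pts, eps, ms)
                # core/noise structure must agree exactly; border points may
                # legitimately attach to either adjacent cluster
                assert np.mean((got == -1) == (want == -1)) > 0.99

    def test_precomputed_matrix_route(self):
        rng = np.random.default_rng(10)
        pts = np.concatenate([
            rng.normal([0, 0, 0], 0.3, size=(30, 3)),
            rng.normal([15, 0, 0], 0.3, size=(30, 3)),
        ])
        res = dbscan(pairwise_rmsd_matrix(pts), eps=1.5, min_samples=4,
                     precomputed=True, points=pts)
        assert res.n_clusters == 2

    def test_bad_parameters(self):
        with pytest.raises(ParameterError):
            dbscan(np.zeros((3, 3)), eps=0.0)
        with pytest.raises(ParameterError):
            dbscan(np.zeros((3, 3)), eps=1.0, min_samples=0)


# ---------------------------------------------------------------------------
# pocket volume
# ---------------------------------------------------------------------------


class TestPocketVolume:
    def test_empty_sphere_analytic(self):
        v = pocket_volume(np.zeros((0, 3)), np.zeros(0), np.zeros(3),
                          radius=9.0, grid_spacing=0.5)
        analytic = 4.0 / 3.0 * np.pi * 9.0**3
        assert abs(v - analytic) / analytic < 0.02

    def test_fully_occluded(self):
        v = pocket_volume(np.zeros((1, 3)), np.array([20.0]), np.zeros(3),
                          radius=9.0, grid_spacing=0.5, atom_padding=0.0)
        assert v == 0.0

    def test_matches_monte_carlo(self):
        """Random occluders: grid volume within 3% of a 1e6-sample MC
        estimate of the same region."""
        rng = np.random.default_rng(12)
        atoms = rng.uniform(-8, 8, size=(30, 3))
        radii = rng.uniform(1.2, 2.0, size=30)
        padding = 1.09
        v = pocket_volume(atoms, radii, np.zeros(3), radius=9.0,
                          grid_spacing=0.5, atom_padding=padding)
        samples = rng.normal(size=(1_000_000, 3))
        samples /= np.linalg.norm(samples, axis=1)[:, None]
        samples *= 9.0 * rng.uniform(0, 1, size=1_000_000)[:, None] ** (1 / 3)
        d = np.linalg.norm(samples[:, None, :] - atoms[None], axis=-1)
        free = np.all(d > (radii + padding)[None, :], axis=1)
        mc = free.mean() * 4.0 / 3.0 * np.pi * 9.0**3
        assert abs(v - mc) / mc < 0.03

    def test_monotone_in_atoms_and_padding(self):
        rng = np.random.default_rng(13)
        atoms = rng.uniform(-6, 6, size=(20, 3))
        radii = np.full(20, 1.5)
        prev = np.inf
        for k in [0, 5, 10, 20]:
            v = pocket_volume(atoms[:k], radii[:k], np.zeros(3), radius=8.0,
                              grid_spacing=0.8)
            assert v <= prev + 1e-9
            prev = v
        vols = [pocket_volume(atoms, radii, np.zeros(3), radius=8.0,
                              grid_spacing=0.8, atom_padding=p)
                for p in [0.0, 0.5, 1.09, 2.0]]
        assert all(a >= b - 1e-9 for a, b in zip(vols, vols[1:]))

    def test_never_exceeds_sphere_volume(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            r = rng.uniform(3, 10)
            h = rng.uniform(0.3, r / 3)
            atoms = rng.uniform(-r, r, size=(5, 3))
            v = pocket_volume(atoms, np.full(5, 1.5), np.zeros(3),
                              radius=r, grid_spacing=h)
            assert 0.0 <= v <= 4.0 / 3.0 * np.pi * r**3 * 1.02

    def test_bad_parameters(self):
        with pytest.raises(ParameterError):
            pocket_volume(np.zeros((0, 3)), np.zeros(0), np.zeros(3),
                          radius=9.0, grid_spacing=0.0)
        with pytest.raises(ParameterError):
            pocket_volume(np.zeros((0, 3)), np.zeros(0), np.zeros(3),
                          radius=-1.0)


class TestVolumeSeries:
    def test_static_frames_constant(self):
        topo = [atom(1, 1, [3, 0, 0]), atom(2, 2, [0, 3, 0])]
        frame = np.array([a.position for a in topo])
        traj = static_traj([frame] * 4, topo)
        series = volume_series(traj, center=np.zeros(3), radius=6.0, grid_spacing=0.5)
        assert np.all(series.values == series.values[0])

    def test_widened_funnel_opens_the_pocket(self):
        """An opened-up vestibule (scaled funnel) has a larger mean
        orthosteric volume than the compact geometry."""
        vols = {}
        for scale in (1.0, 1.4):
            system = build_receptor_model(seed=1, funnel_scale=scale)
            pocket = next(w.center for w in system.potential.wells
                          if w.label == "orthosteric")
            rec = system.receptor_positions
            radii = np.array([a.vdw_radius for a in system.receptor_atoms])
            # the inclusion sphere must sit inside the pocket walls for the
            # comparison to probe the pocket rather than bulk solvent
            vols[scale] = pocket_volume(rec, radii, pocket, radius=6.0,
                                        grid_spacing=0.5)
        assert vols[1.4] > vols[1.0]

    def test_ligand_centroid_mode_follows_the_ligand(self):
        topo = [atom(1, 1, [0, 0, 0], chain="R", vdw=2.0),
                atom(2, 2, [40, 0, 0], chain="L")]
        frames = [np.array([[0, 0, 0], [40.0, 0, 0]]),
                  np.array([[0, 0, 0], [0.5, 0, 0]])]
        traj = static_traj(frames, topo)
        series = volume_series(traj, ligand_selection=np.array([1]),
                               radius=5.0, grid_spacing=0.5)
        # far from the receptor the sphere is empty space; on top of it,
        # the atom eats part of the sphere
        assert series.values[0] > series.values[1]


# ---------------------------------------------------------------------------
# contacts & energies
# ---------------------------------------------------------------------------


class TestContacts:
    def test_near_and_far_residues(self):
        topo = [atom(1, 1, [2, 0, 0]), atom(2, 2, [50, 0, 0]),
                atom(3, 9, [0, 0, 0], chain="L")]
        frame = np.array([a.position for a in topo])
        traj = static_traj([frame] * 3, topo)
        table = contact_frequencies(traj, np.array([2]), [1, 2], cutoff=4.5)
        freq = dict(zip(table.residue_ids, table.frequencies))
        assert freq[1] == 1.0 and freq[2] == 0.0

    def test_half_time_contact(self):
        topo = [atom(1, 1, [2, 0, 0]), atom(2, 9, [0, 0, 0], chain="L")]
        near = np.array([[2.0, 0, 0], [0, 0, 0]])
        far = np.array([[2.0, 0, 0], [30.0, 0, 0]])
        traj = static_traj([near] * 5 + [far] * 5, topo)
        table = contact_frequencies(traj, np.array([1]), [1], cutoff=4.5)
        assert table.frequencies[0] == 0.5
        assert table.counts[0] == 5

    def test_brute_force_and_frame_order_invariance(self):
        rng = np.random.default_rng(15)
        topo = ([atom(i + 1, i + 1, [0, 0, 0]) for i in range(4)]
                + [atom(5, 9, [0, 0, 0], chain="L")])
        frames = rng.uniform(0, 10, size=(12, 5, 3))
        traj = static_traj(frames, topo)
        table = contact_frequencies(traj, np.array([4]), [1, 2, 3, 4], cutoff=4.5)
        # brute force
        for j, resid in enumerate(table.residue_ids):
            count = sum(
                1 for f in frames
                if np.linalg.norm(f[resid - 1] - f[4]) < 4.5
            )
            assert table.counts[j] == count
        shuffled = static_traj(frames[::-1].copy(), topo)
        table2 = contact_frequencies(shuffled, np.array([4]), [1, 2, 3, 4], cutoff=4.5)
        assert np.array_equal(table.counts, table2.counts)

    def test_errors(self):
        topo = [atom(1, 1, [0, 0, 0])]
        traj = static_traj([np.zeros((1, 3))], topo)
        with pytest.raises(SelectionError):
            contact_frequencies(traj, np.zeros(0, dtype=int), [1])
        with pytest.raises(SelectionError):
            contact_frequencies(traj, np.array([0]), [42])

    def test_polar_plot_writes_file(self, tmp_path):
        table = contact_frequencies(
            static_traj([np.array([[2.0, 0, 0], [0, 0, 0]])],
                        [atom(1, 1, [2, 0, 0]), atom(2, 9, [0, 0, 0], chain="L")]),
            np.array([1]), [1],
        )
        out = tmp_path / "polar.png"
        plot_contact_polar(table, path=str(out))
        assert out.exists()


class TestNonbondedEnergy:
    def test_coulomb_constant(self):
        spec = PotentialSpec(
            bead_positions=np.array([[1.0, 0.0, 0.0]]),
            bead_epsilon=0.0,
            bead_charges=np.array([1.0]),
            ligand_charge=1.0,
        )
        elec, _ = nonbonded_energy(np.zeros((1, 3)), spec)
        assert elec == pytest.approx(332.0636)

    def test_neutral_system_no_electrostatics(self, funnel_system):
        elec, _ = nonbonded_energy(np.array([[40.0, 40.0, 40.0]]),
                                   funnel_system.potential)
        assert elec == 0.0

    def test_decomposition_matches_total_potential(self):
        rng = np.random.default_rng(16)
        spec = PotentialSpec(
            wells=[Well(rng.normal(size=3), 5.0, 2.0)],
            bead_positions=rng.normal(scale=5.0, size=(8, 3)),
            bead_charges=rng.normal(size=8),
            ligand_charge=0.5,
            dielectric=4.0,
        )
        p = np.array([6.0, -2.0, 1.0])
        elec, vdw = nonbonded_energy(p[None, :], spec)
        assert elec + vdw == pytest.approx(potential_energy(spec, p), abs=1e-10)


def test_coordination_counting():
    rng = np.random.default_rng(17)
    center = np.array([1.0, 2.0, 3.0])
    inner = center + 2.4 * _unit(rng, 5)
    outer = center + 6.0 * _unit(rng, 7)
    pts = np.concatenate([inner, outer])
    assert coordination_number(pts, center, cutoff=3.0) == 5


def _unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


class TestVolumeProperties:
    """The inclusion-sphere bound holds for arbitrary valid parameters."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        radius=st.floats(2.0, 10.0),
        spacing=st.floats(0.4, 1.5),
        n_atoms=st.integers(0, 12),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_by_sphere_volume(self, radius, spacing, n_atoms, seed):
        if spacing >= radius:
            spacing = 0.4 * radius
        rng = np.random.default_rng(seed)
        atoms = rng.uniform(-radius, radius, size=(n_atoms, 3))
        v = pocket_volume(atoms, np.full(n_atoms, 1.5), np.zeros(3),
                          radius=radius, grid_spacing=spacing)
        assert 0.0 <= v <= 4.0 / 3.0 * np.pi * radius**3 * 1.05
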