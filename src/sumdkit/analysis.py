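"""Trajectory post-processing.

Implements the analysis stack used to characterise binding-pathway
trajectories: Kabsch superposition and RMSD series against a reference pose,
pairwise-RMSD matrices with DBSCAN clustering of ligand/ion positions
(to map where a diffusing species stations along its pathway), POVME-style
grid-based pocket volume inside a spherical inclusion region, per-residue
ligand contact frequencies, and the toy non-bonded interaction-energy
decomposition.

All operations take plain numpy arrays or the lightweight
:class:`Trajectory` container, so they apply equally to the built-in engine's
output and to externally produced coordinates.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from sklearn.cluster import DBSCAN

from .errors import GeometryError, ParameterError, SelectionError
from .model import AtomRecord, PotentialSpec, ToySystem
from .units import COULOMB_CONSTANT, REPULSION_CAP

__all__ = [
    "Trajectory",
    "RMSDSeries",
    "ClusterResult",
    "VolumeSeries",
    "ContactTable",
    "select_atoms",
    "kabsch_superpose",
    "rmsd_series",
    "pairwise_rmsd_matrix",
    "dbscan",
    "pocket_volume",
    "volume_series",
    "contact_frequencies",
    "nonbonded_energy",
    "coordination_number",
    "plot_contact_polar",
]


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``times`` is in ps and must
    be strictly increasing; ``stride`` records the saving interval.
    """

    times: np.ndarray
    coords: np.ndarray
    topology: list[AtomRecord]
    stride: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ParameterError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ParameterError("times and coords disagree on frame count")
        if self.topology and self.coords.shape[1] != len(self.topology):
            raise ParameterError("topology and coords disagree on atom count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_segments(cls, segments, system: ToySystem) -> "Trajectory":
        """Assemble a full-topology trajectory from engine segments.

        The frozen receptor coordinates are repeated in every frame so that
        analysis operations see complete structures.
        """
        segments = [s for s in segments if s.n_frames]
        if not segments:
            raise ParameterError("no frames in any segment")
        times = np.concatenate([s.times for s in segments])
        lig = np.concatenate([s.positions for s in segments])
        rec = system.receptor_positions
        coords = np.concatenate(
            [np.broadcast_to(rec, (len(times),) + rec.shape), lig], axis=1
        )
        stride = float(times[1] - times[0]) if len(times) > 1 else 0.0
        return cls(times=times, coords=coords, topology=system.topology, stride=stride)


@dataclass
class RMSDSeries:
    """Per-frame RMSD (A) against one reference, plus its minimum."""

    values: np.ndarray
    reference_label: str = ""
    times: np.ndarray | None = None
    rmsd_min: float = field(init=False)
    argmin_frame: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size == 0:
            raise ParameterError("empty RMSD series")
        if np.any(self.values < 0):
            raise ParameterError("RMSD values must be non-negative")
        self.argmin_frame = int(np.argmin(self.values))
        self.rmsd_min = float(self.values[self.argmin_frame])


@dataclass
class ClusterResult:
    """DBSCAN labelling of per-frame positions (-1 = noise)."""

    labels: np.ndarray
    eps: float
    min_samples: int
    cluster_centroids: np.ndarray | None = None
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        self.n_clusters = int(len(set(self.labels[self.labels >= 0])))


@dataclass
class VolumeSeries:
    """Per-frame pocket volume (A^3) inside a spherical inclusion region."""

    values: np.ndarray
    center_mode: str
    radius: float
    grid_spacing: float
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        vmax = 4.0 / 3.0 * np.pi * self.radius**3
        if np.any(self.values < 0) or np.any(self.values > vmax + 1e-9):
            raise ParameterError("volumes must lie in [0, (4/3) pi r^3]")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class ContactTable:
    """Per-residue ligand contact counts and frequencies."""

    residue_ids: list[int]
    counts: np.ndarray
    n_frames: int
    cutoff: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int).reshape(-1)
        if len(self.residue_ids) != self.counts.size:
            raise ParameterError("residue_ids and counts disagree")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / float(self.n_frames)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


def select_atoms(
    topology: list[AtomRecord],
    residue_ids: list[int] | None = None,
    name_glob: str | None = None,
    chain: str | None = None,
) -> np.ndarray:
    """Resolve a residue-id list / atom-name glob / chain filter to indices."""
    idx = []
    wanted = set(residue_ids) if residue_ids is not None else None
    for i, atom in enumerate(topology):
        if wanted is not None and atom.residue_id not in wanted:
            continue
        if name_glob is not None and not fnmatch.fnmatch(atom.name, name_glob):
            continue
        if chain is not None and atom.chain != chain:
            continue
        idx.append(i)
    if wanted is not None:
        present = {topology[i].residue_id for i in idx}
        missing = sorted(wanted - {a.residue_id for a in topology})
        if missing:
            raise SelectionError(f"residue ids not in topology: {missing}")
        del present
    if not idx:
        raise SelectionError("selection resolved to zero atoms")
    return np.asarray(idx, dtype=int)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with ``x' = R @ x + t`` the
    transformed mobile coordinates and ``rmsd`` the (weighted) RMSD after
    superposition. The rotation is always proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise GeometryError("mobile and reference must have equal point counts")
    if mob.shape[0] < 3:
        raise GeometryError("superposition requires at least 3 points")
    w = np.ones(mob.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ParameterError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mc = np.average(mob, axis=0, weights=w)
    rc = np.average(ref, axis=0, weights=w)
    mob_c = mob - mc
    ref_c = ref - rc
    if min(np.linalg.matrix_rank(mob_c, tol=1e-8), np.linalg.matrix_rank(ref_c, tol=1e-8)) < 2:
        raise GeometryError("degenerate (collinear) point configuration")

    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    rmat = rot.as_matrix()
    translation = rc - rmat @ mc
    moved = mob_c @ rmat.T + rc
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - ref) ** 2, axis=1))))
    return rmat, translation, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray,
    reference_label: str = "reference",
) -> RMSDSeries:
    """Per-frame RMSD of ``measure_selection`` after fitting ``fit_selection``.

    Mirrors the usual crystallographic-pose comparison: each frame is
    superposed on the reference over the fit atoms (e.g. the receptor), and
    the RMSD is reported over the measured atoms (e.g. the ligand or ion).
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if ref.shape[0] != traj.n_atoms:
        raise SelectionError("reference must cover the full topology")
    fit = np.asarray(fit_selection, dtype=int)
    meas = np.asarray(measure_selection, dtype=int)
    if fit.size == 0 or meas.size == 0:
        raise SelectionError("empty selection")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rmat, t, _ = kabsch_superpose(traj.coords[i, fit], ref[fit])
        moved = traj.coords[i, meas] @ rmat.T + t
        values[i] = np.sqrt(np.mean(np.sum((moved - ref[meas]) ** 2, axis=1)))
    return RMSDSeries(values=values, reference_label=reference_label, times=traj.times)


def pairwise_rmsd_matrix(points: np.ndarray) -> np.ndarray:
    """nf x nf coordinate-RMSD matrix between frames.

    ``points`` is (nf, 3) for a single particle (ion) or (nf, n_atoms, 3) for
    a multi-atom ligand; positions are assumed already expressed in the
    receptor frame, so no re-superposition is performed. For a single
    particle this is the Euclidean distance matrix.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ParameterError("empty input")
    if pts.ndim == 2 and pts.shape[1] == 3:
        pts = pts[:, None, :]
    if pts.ndim != 3 or pts.shape[-1] != 3:
        raise ParameterError("points must be (nf, 3) or (nf, n_atoms, 3)")
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 frames")
    nf, na, _ = pts.shape
    flat = pts.reshape(nf, 3 * na)
    return cdist(flat, flat) / np.sqrt(na)


def dbscan(
    data: np.ndarray,
    eps: float = 1.5,
    min_samples: int = 5,
    *,
    precomputed: bool = False,
    points: np.ndarray | None = None,
) -> ClusterResult:
    """Density-based clustering of positions (standard DBSCAN semantics).

    ``data`` is either an (n, 3) array of positions or, with
    ``precomputed=True``, an (n, n) pairwise-RMSD/distance matrix (pass
    ``points`` as well to get cluster centroids). Noise is labelled -1.
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    arr = np.asarray(data, dtype=float)
    metric = "precomputed" if precomputed else "euclidean"
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric=metric).fit_predict(arr)
    pos = points if precomputed else arr
    centroids = None
    if pos is not None:
        pos = np.asarray(pos, dtype=float).reshape(len(labels), -1)
        uniq = sorted(set(labels[labels >= 0]))
        if uniq:
            centroids = np.stack([pos[labels == k].mean(axis=0) for k in uniq])
    return ClusterResult(
        labels=labels, eps=eps, min_samples=min_samples, cluster_centroids=centroids
    )


def pocket_volume(
    atom_positions: np.ndarray,
    vdw_radii: np.ndarray,
    center: np.ndarray,
    radius: float = 9.0,
    grid_spacing: float = 1.0,
    atom_padding: float = 1.09,
) -> float:
    """POVME-style pocket volume (A^3) inside a spherical inclusion region.

    A cubic lattice of spacing ``grid_spacing`` covers the sphere of
    ``radius`` around ``center``; lattice points inside the sphere but
    outside every atom's ``vdw_radius + atom_padding`` sphere are counted and
    multiplied by the lattice cell volume. The default 1.09 A padding is the
    customary hydrogen-probe allowance.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if not 0 < grid_spacing < radius:
        raise ParameterError("grid_spacing must lie in (0, radius)")
    if atom_padding < 0:
        raise ParameterError("atom_padding must be >= 0")
    center = np.asarray(center, dtype=float).reshape(3)

    n = int(np.floor(radius / grid_spacing))
    axis = np.arange(-n, n + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = grid[np.einsum("ij,ij->i", grid, grid) <= radius**2]
    grid = grid + center

    pos = np.asarray(atom_positions, dtype=float).reshape(-1, 3)
    if pos.shape[0]:
        radii = np.asarray(vdw_radii, dtype=float).reshape(-1)
        if radii.size != pos.shape[0]:
            raise ParameterError("vdw_radii length must match atom_positions")
        tree = cKDTree(grid)
        occluded = np.zeros(len(grid), dtype=bool)
        for p, r in zip(pos, radii + atom_padding):
            occluded[tree.query_ball_point(p, r)] = True
        grid = grid[~occluded]
    return float(len(grid) * grid_spacing**3)


def volume_series(
    traj: Trajectory,
    *,
    center: np.ndarray | None = None,
    ligand_selection: np.ndarray | None = None,
    receptor_selection: np.ndarray | None = None,
    radius: float = 9.0,
    grid_spacing: float = 1.0,
    atom_padding: float = 1.09,
) -> VolumeSeries:
    """Track pocket volume over frames.

    The inclusion sphere is centered either on a fixed point (``center``) or
    on the per-frame ligand centroid (``ligand_selection``), the convention
    used when following an agonist into its pocket. Occluding atoms default
    to everything outside the ligand selection.
    """
    if (center is None) == (ligand_selection is None):
        raise ParameterError("provide exactly one of center / ligand_selection")
    if receptor_selection is None:
        if ligand_selection is not None:
            mask = np.ones(traj.n_atoms, dtype=bool)
            mask[np.asarray(ligand_selection, dtype=int)] = False
            receptor_selection = np.nonzero(mask)[0]
        else:
            receptor_selection = np.arange(traj.n_atoms)
    receptor_selection = np.asarray(receptor_selection, dtype=int)
    radii = np.array([traj.topology[i].vdw_radius for i in receptor_selection])

    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        c = (
            np.asarray(center, dtype=float)
            if center is not None
            else traj.coords[i, ligand_selection].mean(axis=0)
        )
        values[i] = pocket_volume(
            traj.coords[i, receptor_selection], radii, c, radius, grid_spacing, atom_padding
        )
    mode = "fixed" if center is not None else "ligand_centroid"
    return VolumeSeries(
        values=values,
        center_mode=mode,
        radius=radius,
        grid_spacing=grid_spacing,
        times=traj.times,
    )


def contact_frequencies(
    traj: Trajectory,
    ligand_selection: np.ndarray,
    receptor_residues: list[int],
    cutoff: float = 4.5,
) -> ContactTable:
    """Fraction of frames in which each residue contacts the ligand.

    A residue is in contact in a frame iff any of its atoms lies within
    ``cutoff`` (A, strict) of any ligand atom — the cumulative-contact-map
    convention for heavy atoms.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    lig = np.asarray(ligand_selection, dtype=int)
    if lig.size == 0:
        raise SelectionError("empty ligand selection")
    groups: dict[int, list[int]] = {}
    for resid in receptor_residues:
        idx = [i for i, a in enumerate(traj.topology) if a.residue_id == resid]
        if not idx:
            raise SelectionError(f"residue id {resid} not in topology")
        groups[resid] = idx

    resids = list(groups)
    counts = np.zeros(len(resids), dtype=int)
    for i in range(traj.n_frames):
        lpos = traj.coords[i, lig]
        for j, resid in enumerate(resids):
            rpos = traj.coords[i, groups[resid]]
            if cdist(lpos, rpos).min() < cutoff:
                counts[j] += 1
    return ContactTable(
        residue_ids=resids, counts=counts, n_frames=traj.n_frames, cutoff=cutoff
    )


def nonbonded_energy(
    ligand_positions: np.ndarray, spec: PotentialSpec
) -> tuple[float, float]:
    """Toy ligand-receptor interaction energy split (kcal/mol).

    Returns ``(electrostatic, vdw_like)`` where the electrostatic term is the
    pairwise Coulomb sum ``332.0636 * q1*q2 / (eps_r * r)`` and the vdW-like
    term collects the spec's attractive wells and clamped bead repulsions.
    Their sum equals :func:`sumdkit.model.potential_energy` summed over the
    ligand beads.
    """
    pts = np.asarray(ligand_positions, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ParameterError("empty ligand positions")

    vdw = 0.0
    centers, depths, widths = spec.well_arrays()
    if len(depths):
        d2 = np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        vdw -= float(np.sum(depths * np.exp(-d2 / (2.0 * widths**2))))

    elec = 0.0
    if spec.bead_positions.shape[0]:
        r = cdist(pts, spec.bead_positions)
        with np.errstate(divide="ignore", over="ignore"):
            rep = spec.bead_epsilon * (spec.bead_sigma / r) ** 12
        vdw += float(np.sum(np.minimum(rep, REPULSION_CAP)))
        if spec.has_coulomb:
            elec = float(
                np.sum(
                    COULOMB_CONSTANT
                    * spec.ligand_charge
                    * spec.bead_charges[None, :]
                    / (spec.dielectric * np.maximum(r, 1e-6))
                )
            )
    return elec, vdw


def coordination_number(
    positions: np.ndarray, center: np.ndarray, cutoff: float
) -> int:
    """Count positions strictly within ``cutoff`` A of ``center``.

    The classic use is counting coordinating oxygens around a bound ion.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    center = np.asarray(center, dtype=float).reshape(3)
    return int(np.sum(np.linalg.norm(pos - center, axis=1) < cutoff))


def plot_contact_polar(table: ContactTable, path: str | None = None, ax=None):
    """Polar bar diagram of per-residue contact frequencies (thin layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(table.residue_ids)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ax.bar(theta, table.frequencies, width=2.0 * np.pi / max(n, 1), alpha=0.7)
    ax.set_xticks(theta)
    ax.set_xticklabels([str(r) for r in table.residue_ids], fontsize=7)
    ax.set_ylim(0, 1)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax
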