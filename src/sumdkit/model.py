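"""Coarse-grained receptor-ligand systems and their analytic potential.

The built-in test system is a bead-model "receptor" whose geometry echoes the
topology of a class-A GPCR binding problem without pretending to be one: a
funnel of repulsive beads leads from bulk solvent down to an orthosteric
pocket (the global minimum of the potential), a shallower *meta-binding* well
sits on the funnel rim as a solvent-exposed decoy, and a narrow bead-lined
channel below the pocket opens onto a deeper *allosteric* well, mimicking an
ion pocket buried in the helical bundle.

The potential is a sum of isotropic attractive Gaussian wells, one per site,
and a soft-sphere ``eps*(sigma/r)**12`` repulsion per receptor bead (clamped
at :data:`sumdkit.units.REPULSION_CAP` so bead centers are finite), plus an
optional Coulomb term. Everything is analytic and smooth, so forces are exact
gradients — the property the integrator and its energy-conservation checks
rely on.

Receptor beads are frozen; receptor flexibility is emulated by the
``funnel_scale`` switch, which widens the funnel mouth and the pocket wall
radius (used to contrast "compact" and "opened-up" pocket volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .units import COULOMB_CONSTANT, REPULSION_CAP

__all__ = [
    "AtomRecord",
    "Well",
    "PotentialSpec",
    "ToySystem",
    "build_receptor_model",
    "potential_energy",
    "potential_forces",
    "neutralizing_counterions",
]


@dataclass
class AtomRecord:
    """One atom (or coarse-grained bead) of a structure.

    Positions are in A, masses in amu, charges in elementary charges and
    van der Waals radii in A.
    """

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    mass: float
    charge: float = 0.0
    vdw_radius: float = 1.70

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ParameterError(f"atom {self.serial}: non-finite position")
        if self.serial <= 0:
            raise ParameterError(f"atom serial must be positive, got {self.serial}")
        if self.mass <= 0:
            raise ParameterError(f"atom {self.serial}: mass must be > 0")
        if self.vdw_radius <= 0:
            raise ParameterError(f"atom {self.serial}: vdw_radius must be > 0")


@dataclass
class Well:
    """Isotropic Gaussian attractive well: U = -depth * exp(-|r-c|^2 / (2 w^2))."""

    center: np.ndarray
    depth: float
    width: float
    label: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.depth <= 0:
            raise ParameterError(f"well depth must be > 0, got {self.depth}")
        if self.width <= 0:
            raise ParameterError(f"well width must be > 0, got {self.width}")


@dataclass
class PotentialSpec:
    """Analytic potential felt by the ligand.

    ``bead_positions`` holds the frozen receptor bead centers; each bead
    contributes a clamped soft-sphere repulsion. ``bead_charges`` together
    with ``ligand_charge`` switch on an optional Coulomb term with a uniform
    ``dielectric``.
    """

    wells: list[Well] = field(default_factory=list)
    bead_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    bead_epsilon: float = 1.0
    bead_sigma: float = 2.5
    bead_charges: np.ndarray | None = None
    ligand_charge: float = 0.0
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        self.bead_positions = np.asarray(self.bead_positions, dtype=float).reshape(-1, 3)
        if self.bead_epsilon < 0 or self.bead_sigma <= 0:
            raise ParameterError("bead repulsion requires epsilon >= 0 and sigma > 0")
        if self.bead_charges is not None:
            self.bead_charges = np.asarray(self.bead_charges, dtype=float).reshape(-1)
            if self.bead_charges.shape[0] != self.bead_positions.shape[0]:
                raise ParameterError("bead_charges length must match bead_positions")
        if self.dielectric <= 0:
            raise ParameterError("dielectric must be > 0")

    # dense views used by the integrator kernel
    def well_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.wells:
            return np.zeros((0, 3)), np.zeros(0), np.ones(0)
        centers = np.stack([w.center for w in self.wells])
        depths = np.array([w.depth for w in self.wells])
        widths = np.array([w.width for w in self.wells])
        return centers, depths, widths

    @property
    def has_coulomb(self) -> bool:
        return self.bead_charges is not None and self.ligand_charge != 0.0


@dataclass
class ToySystem:
    """A frozen bead receptor plus a mobile (rigid) ligand in a box.

    ``site_definitions`` maps a site name (e.g. ``"orthosteric"``) to the
    residue ids of the receptor beads whose mass-weighted centroid defines the
    site center used by the supervision loop. The box has reflecting walls.
    """

    receptor_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    site_definitions: dict[str, list[int]]
    box: np.ndarray
    potential: PotentialSpec

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ParameterError("box edges must be positive")
        known = {a.residue_id for a in self.receptor_atoms}
        for site, resids in self.site_definitions.items():
            missing = [r for r in resids if r not in known]
            if missing:
                raise ParameterError(
                    f"site {site!r} references missing residue ids {missing}"
                )
        serials = [a.serial for a in self.receptor_atoms + self.ligand_atoms]
        if len(serials) != len(set(serials)):
            raise ParameterError("atom serials must be unique within a system")

    @property
    def receptor_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.receptor_atoms]).reshape(-1, 3)

    @property
    def ligand_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand_atoms]).reshape(-1, 3)

    @property
    def ligand_masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.ligand_atoms])

    @property
    def topology(self) -> list[AtomRecord]:
        """Receptor atoms followed by ligand atoms (frame atom order)."""
        return list(self.receptor_atoms) + list(self.ligand_atoms)


def potential_energy(spec: PotentialSpec, position: np.ndarray) -> float | np.ndarray:
    """Potential energy (kcal/mol) of a point ligand bead at ``position``.

    ``position`` may be a single 3-vector or an ``(..., 3)`` array of points;
    the return value broadcasts accordingly.
    """
    pos = np.asarray(position, dtype=float)
    if pos.shape[-1] != 3:
        raise ParameterError("position must have a trailing dimension of 3")
    if not np.all(np.isfinite(pos)):
        raise ParameterError("position must be finite")
    scalar = pos.ndim == 1
    pts = pos.reshape(-1, 3)
    energy = np.zeros(pts.shape[0])

    centers, depths, widths = spec.well_arrays()
    if len(depths):
        d2 = np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        energy -= np.sum(depths * np.exp(-d2 / (2.0 * widths**2)), axis=-1)

    if spec.bead_positions.shape[0]:
        disp = pts[:, None, :] - spec.bead_positions[None, :, :]
        r = np.sqrt(np.sum(disp**2, axis=-1))
        with np.errstate(divide="ignore", over="ignore"):
            rep = spec.bead_epsilon * (spec.bead_sigma / r) ** 12
        energy += np.sum(np.minimum(rep, REPULSION_CAP), axis=-1)
        if spec.has_coulomb:
            r_safe = np.maximum(r, 1e-6)
            energy += np.sum(
                COULOMB_CONSTANT
                * spec.ligand_charge
                * spec.bead_charges
                / (spec.dielectric * r_safe),
                axis=-1,
            )
    return float(energy[0]) if scalar else energy.reshape(pos.shape[:-1])


def potential_forces(spec: PotentialSpec, position: np.ndarray) -> np.ndarray:
    """Analytic force -grad U, kcal/(mol*A), at one or many positions."""
    pos = np.asarray(position, dtype=float)
    if pos.shape[-1] != 3:
        raise ParameterError("position must have a trailing dimension of 3")
    if not np.all(np.isfinite(pos)):
        raise ParameterError("position must be finite")
    scalar = pos.ndim == 1
    pts = pos.reshape(-1, 3)
    force = np.zeros_like(pts)

    centers, depths, widths = spec.well_arrays()
    if len(depths):
        disp = pts[:, None, :] - centers[None, :, :]
        d2 = np.sum(disp**2, axis=-1)
        g = depths * np.exp(-d2 / (2.0 * widths**2)) / widths**2
        force -= np.sum(g[:, :, None] * disp, axis=1)

    if spec.bead_positions.shape[0]:
        disp = pts[:, None, :] - spec.bead_positions[None, :, :]
        r2 = np.sum(disp**2, axis=-1)
        r = np.sqrt(r2)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            rep = spec.bead_epsilon * (spec.bead_sigma / r) ** 12
            # force vanishes on the clamped plateau (|U_rep| >= cap) and at r = 0
            mag = np.where(rep < REPULSION_CAP, 12.0 * rep / np.maximum(r2, 1e-300), 0.0)
        force += np.sum(mag[:, :, None] * disp, axis=1)
        if spec.has_coulomb:
            r_safe = np.maximum(r, 1e-6)
            cmag = (
                COULOMB_CONSTANT
                * spec.ligand_charge
                * spec.bead_charges
                / (spec.dielectric * r_safe**3)
            )
            force += np.sum(cmag[:, :, None] * disp, axis=1)
    return force[0] if scalar else force.reshape(pos.shape)


# --------------------------------------------------------------------------
# reference funnel system
# --------------------------------------------------------------------------

_MIN_BEADS = 24

# fixed marker-bead counts: 4 tetrahedral beads ring the orthosteric pocket,
# 3 each the meta and allosteric wells, 8 line the floor channel
_N_FIXED = 4 + 3 + 3 + 8


def _ring(center: np.ndarray, radius: float, n: int, phase: float) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    pts = np.tile(center, (n, 1))
    pts[:, 0] += radius * np.cos(ang)
    pts[:, 1] += radius * np.sin(ang)
    return pts


def build_receptor_model(
    n_beads: int = 50,
    pocket_depth: float = 8.0,
    meta_site_depth: float = 3.0,
    seed: int = 0,
    *,
    funnel_scale: float = 1.0,
    box_edge: float = 80.0,
    ligand_mass: float = 23.0,
    ligand_charge: float = 0.0,
    ligand_start: np.ndarray | None = None,
) -> ToySystem:
    """Build the reference funnel system.

    The orthosteric pocket sits at the bottom of a bead-walled funnel opening
    upward into bulk; a meta-binding well decorates the funnel rim; an
    allosteric well lies below the pocket behind a bead-lined channel. The
    orthosteric well (``pocket_depth``) must be deeper than the meta well so
    that the target site is the global minimum.

    ``funnel_scale`` > 1 widens the funnel mouth and pocket wall radii,
    emulating the extra flexibility of an opened-up extracellular vestibule.
    Deterministic for a fixed ``seed`` (used only to jitter wall beads).
    """
    if pocket_depth <= 0 or meta_site_depth <= 0:
        raise ParameterError("well depths must be positive")
    if pocket_depth <= meta_site_depth:
        raise ParameterError(
            "pocket_depth must exceed meta_site_depth so the orthosteric site "
            "is the global minimum"
        )
    if n_beads < _MIN_BEADS:
        raise ParameterError(
            f"n_beads={n_beads} too small to form a funnel (minimum {_MIN_BEADS})"
        )
    if funnel_scale <= 0:
        raise ParameterError("funnel_scale must be positive")

    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_edge))
    pocket = np.array([box_edge / 2.0, box_edge / 2.0, box_edge / 3.0])
    meta_center = pocket + np.array([13.0, 0.0, 15.0])
    allo_center = pocket + np.array([0.0, 0.0, -7.0])

    beads: list[np.ndarray] = []
    labels: list[str] = []

    # orthosteric pocket markers: tetrahedron of wall beads around the minimum
    tet = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    for v in tet:
        beads.append(pocket + 3.5 * funnel_scale * v)
        labels.append("ORT")
    # meta-site markers: horizontal triangle
    for v in _ring(meta_center, 3.2, 3, phase=0.3):
        beads.append(v)
        labels.append("MET")
    # allosteric markers
    for v in _ring(allo_center, 3.2, 3, phase=0.9):
        beads.append(v)
        labels.append("ALS")
    # floor / channel ring between pocket and allosteric well
    for v in _ring(pocket + np.array([0.0, 0.0, -2.5]), 2.6, 8, phase=0.0):
        beads.append(v)
        labels.append("CHN")

    # funnel wall rings, budgeted over the remaining beads in proportion to
    # ring circumference; jitter keeps the walls from looking crystalline
    ring_z = np.array([2.5, 4.5, 6.5, 8.5])
    ring_r = (3.0 + 0.5 * ring_z) * funnel_scale
    wall_budget = n_beads - _N_FIXED
    counts = np.maximum(2, np.floor(wall_budget * ring_r / ring_r.sum()).astype(int))
    while counts.sum() > wall_budget:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < wall_budget:
        counts[np.argmin(counts)] += 1
    for k, (z, r, n) in enumerate(zip(ring_z, ring_r, counts)):
        ring = _ring(pocket + np.array([0.0, 0.0, z]), r, int(n), phase=0.5 * k)
        ring += rng.normal(0.0, 0.05, size=ring.shape)
        for v in ring:
            beads.append(v)
            labels.append("FUN")

    bead_arr = np.array(beads)
    receptor_atoms = [
        AtomRecord(
            serial=i + 1,
            name="BD",
            residue_name=labels[i],
            residue_id=i + 1,
            chain="R",
            position=bead_arr[i],
            mass=72.0,  # CG bead, ~4 heavy atoms
            vdw_radius=2.5,
        )
        for i in range(len(beads))
    ]

    site_definitions = {
        "orthosteric": [i + 1 for i, lab in enumerate(labels) if lab == "ORT"],
        "meta": [i + 1 for i, lab in enumerate(labels) if lab == "MET"],
        "allosteric": [i + 1 for i, lab in enumerate(labels) if lab == "ALS"],
    }

    wells = [
        Well(pocket, pocket_depth, 2.5, label="orthosteric"),
        Well(meta_center, meta_site_depth, 2.0, label="meta"),
        Well(allo_center, 0.6 * pocket_depth, 1.5, label="allosteric"),
    ]
    charges = np.zeros(len(beads)) if ligand_charge else None
    potential = PotentialSpec(
        wells=wells,
        bead_positions=bead_arr,
        bead_epsilon=1.0,
        bead_sigma=2.5,
        bead_charges=charges,
        ligand_charge=ligand_charge,
    )

    if ligand_start is None:
        ligand_start = np.array([box_edge / 2.0, box_edge / 2.0, box_edge - 10.0])
    ligand_start = np.asarray(ligand_start, dtype=float).reshape(3)
    ligand_atoms = [
        AtomRecord(
            serial=len(beads) + 1,
            name="LIG",
            residue_name="LIG",
            residue_id=len(beads) + 1,
            chain="L",
            position=ligand_start,
            mass=ligand_mass,
            charge=ligand_charge,
            vdw_radius=2.27,
        )
    ]

    system = ToySystem(
        receptor_atoms=receptor_atoms,
        ligand_atoms=ligand_atoms,
        site_definitions=site_definitions,
        box=box,
        potential=potential,
    )
    # the ligand must start outside every defined site (> 5 A, the default
    # supervision threshold)
    masses = np.array([a.mass for a in receptor_atoms])
    for site, resids in site_definitions.items():
        idx = [i for i, a in enumerate(receptor_atoms) if a.residue_id in resids]
        center = np.average(bead_arr[idx], axis=0, weights=masses[idx])
        if np.linalg.norm(ligand_start - center) <= 5.0:
            raise GeometryError(f"ligand_start lies inside site {site!r}")
    return system


def neutralizing_counterions(net_charge: int, n_cations: int = 100) -> tuple[int, int]:
    """Counts of (Na+, Cl-) that neutralise a solute of ``net_charge``.

    Adding ``n_cations`` sodium ions to a solute of positive net charge
    requires ``n_cations + net_charge`` chloride ions for overall neutrality
    (e.g. a +11 receptor with 100 Na+ needs 111 Cl-).
    """
    n_anions = n_cations + net_charge
    if n_anions < 0:
        raise ParameterError("not enough cations to neutralise this net charge")
    return n_cations, n_anions
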