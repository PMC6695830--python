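"""Shared fixtures: toy systems of increasing complexity."""

from __future__ import annotations

import numpy as np
import pytest

from sumdkit import (
    AtomRecord,
    EngineConfig,
    PotentialSpec,
    ToySystem,
    Well,
    build_receptor_model,
)


@pytest.fixture(scope="session")
def funnel_system():
    """The reference funnel system at default construction parameters."""
    return build_receptor_model(seed=1)


@pytest.fixture(scope="session")
def single_well_spec():
    """One isolated Gaussian well (depth 8, width 2) at the origin, no beads."""
    return PotentialSpec(wells=[Well(np.zeros(3), 8.0, 2.0)])


def make_point_system(
    spec: PotentialSpec,
    ligand_position,
    box_edge: float = 200.0,
    ligand_mass: float = 23.0,
    site_center=None,
) -> ToySystem:
    """A bare one-bead-ligand system around an arbitrary potential.

    If ``site_center`` is given, four massless-jitter marker beads around it
    define a ``"target"`` site (their centroid is exactly the center).
    """
    receptor_atoms = []
    sites = {}
    if site_center is not None:
        site_center = np.asarray(site_center, dtype=float)
        offsets = 6.0 * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
        receptor_atoms = [
            AtomRecord(
                serial=i + 1,
                name="BD",
                residue_name="SIT",
                residue_id=i + 1,
                chain="R",
                position=site_center + off,
                mass=72.0,
                vdw_radius=2.5,
            )
            for i, off in enumerate(offsets)
        ]
        sites = {"target": [1, 2, 3, 4]}
    ligand = AtomRecord(
        serial=len(receptor_atoms) + 1,
        name="LIG",
        residue_name="LIG",
        residue_id=len(receptor_atoms) + 1,
        chain="L",
        position=np.asarray(ligand_position, dtype=float),
        mass=ligand_mass,
        vdw_radius=2.27,
    )
    return ToySystem(
        receptor_atoms=receptor_atoms,
        ligand_atoms=[ligand],
        site_definitions=sites,
        box=np.full(3, box_edge),
        potential=spec,
    )


@pytest.fixture()
def fast_engine():
    """Short-stride engine config for cheap tests."""
    return EngineConfig(frame_stride=1.0, seed=0)
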