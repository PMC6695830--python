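"""Minimal NVT Langevin engine satisfying the supervision contract.

The supervision loop only needs an engine that can (a) advance a state for a
fixed duration, returning frames on a fixed stride, (b) expose/restore its
full state including the RNG, and (c) redraw Maxwell-Boltzmann velocities.
This module implements that contract for the toy systems of
:mod:`sumdkit.model`; any external MD engine with the same contract can stand
in.

Integrator: BAOAB Langevin splitting (kick / drift / Ornstein-Uhlenbeck /
drift / kick), which reduces exactly to velocity Verlet when friction and
temperature are zero. The ligand is treated as a single rigid translating
body: forces are summed over its beads and applied to the center of mass; no
internal or rotational degrees of freedom are integrated. Box walls reflect.

Thermostat noise is pre-generated from a numpy ``Generator`` whose state
travels inside :class:`SimState`, so trajectories are bitwise reproducible
and an interrupted run can be continued exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import IntegrationError, ParameterError
from .model import PotentialSpec, ToySystem
from .units import KB, KCAL_TO_AKMA, REPULSION_CAP

__all__ = [
    "EngineConfig",
    "SimState",
    "TrajectorySegment",
    "sample_velocities",
    "initial_state",
    "run_segment",
]


@dataclass
class EngineConfig:
    """Integrator settings.

    Defaults follow common GPCR production-run practice: a 2 fs time step, a
    Langevin thermostat at 310 K with a low 1 ps^-1 damping, and frames saved
    every 20 ps.
    """

    dt: float = 0.002  # ps
    temperature: float = 310.0  # K
    friction: float = 1.0  # ps^-1
    frame_stride: float = 20.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.temperature < 0:
            raise ParameterError("temperature must be >= 0")
        if self.friction < 0:
            raise ParameterError("friction must be >= 0")
        steps = self.frame_stride / self.dt
        if self.frame_stride <= 0 or abs(steps - round(steps)) > 1e-9 * steps:
            raise ParameterError("frame_stride must be a positive integer multiple of dt")

    @property
    def steps_per_frame(self) -> int:
        return int(round(self.frame_stride / self.dt))


@dataclass
class SimState:
    """Full dynamical state: positions, velocities, clock and RNG."""

    time: float
    positions: np.ndarray  # (n_ligand_atoms, 3), A
    velocities: np.ndarray  # (n_ligand_atoms, 3), A/ps
    rng_state: dict | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if self.positions.shape != self.velocities.shape:
            raise ParameterError("positions and velocities must have equal shapes")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise ParameterError("state contains non-finite values")

    def copy(self) -> "SimState":
        return SimState(
            time=self.time,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            rng_state=None if self.rng_state is None else dict(self.rng_state),
        )


@dataclass
class TrajectorySegment:
    """Frames produced by one engine call (one supervision window)."""

    times: np.ndarray  # (nf,), ps
    positions: np.ndarray  # (nf, n_ligand_atoms, 3), A
    start_state: SimState
    end_state: SimState
    window_index: int = 0
    frame_velocities: np.ndarray | None = None  # (nf, 3) body COM velocity

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ParameterError("times and positions must have equal frame counts")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def sample_velocities(
    masses: np.ndarray, temperature: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocity draw, one 3-vector per atom (A/ps).

    Each component is a zero-mean normal with variance k_B T / m. At T = 0
    the draw is identically zero. Deterministic for a fixed integer seed;
    passing a ``Generator`` advances that stream instead.
    """
    masses = np.asarray(masses, dtype=float).reshape(-1)
    if np.any(masses <= 0):
        raise ParameterError("masses must be positive")
    if temperature < 0:
        raise ParameterError("temperature must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature * KCAL_TO_AKMA / masses)
    return rng.standard_normal((masses.size, 3)) * sigma[:, None]


def initial_state(system: ToySystem, config: EngineConfig) -> SimState:
    """Starting state: ligand at its build position, thermalised velocities."""
    rng = np.random.default_rng(config.seed)
    vel = sample_velocities(system.ligand_masses, config.temperature, rng)
    return SimState(
        time=0.0,
        positions=system.ligand_positions,
        velocities=vel,
        rng_state=rng.bit_generator.state,
    )


@njit(cache=False)
def _baoab(
    com,
    vel,
    offsets,
    total_mass,
    noise,
    dt,
    c1,
    c2,
    well_c,
    well_d,
    well_w,
    bead_pos,
    eps,
    sigma,
    bead_q,
    q_lig,
    dielectric,
    box,
    save_every,
    frames_com,
    frames_vel,
):  # pragma: no cover - exercised through run_segment
    n_steps = noise.shape[0]
    n_off = offsets.shape[0]
    n_wells = well_c.shape[0]
    n_beads = bead_pos.shape[0]
    use_coulomb = bead_q.shape[0] > 0 and q_lig != 0.0
    sigma12 = sigma**12
    kfac = KCAL_TO_AKMA / total_mass
    f = np.zeros(3)

    # force at current com
    def _force(com, f):
        f[0] = 0.0
        f[1] = 0.0
        f[2] = 0.0
        for a in range(n_off):
            px = com[0] + offsets[a, 0]
            py = com[1] + offsets[a, 1]
            pz = com[2] + offsets[a, 2]
            for j in range(n_wells):
                dx = px - well_c[j, 0]
                dy = py - well_c[j, 1]
                dz = pz - well_c[j, 2]
                w2 = well_w[j] * well_w[j]
                g = well_d[j] * math.exp(-(dx * dx + dy * dy + dz * dz) / (2.0 * w2)) / w2
                f[0] -= g * dx
                f[1] -= g * dy
                f[2] -= g * dz
            for b in range(n_beads):
                dx = px - bead_pos[b, 0]
                dy = py - bead_pos[b, 1]
                dz = pz - bead_pos[b, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > 0.0:
                    rep = eps * sigma12 / r2**6
                    if rep < REPULSION_CAP:
                        mag = 12.0 * rep / r2
                        f[0] += mag * dx
                        f[1] += mag * dy
                        f[2] += mag * dz
                    if use_coulomb:
                        r = math.sqrt(r2)
                        if r < 1e-6:
                            r = 1e-6
                        cmag = 332.0636 * q_lig * bead_q[b] / (dielectric * r * r * r)
                        f[0] += cmag * dx
                        f[1] += cmag * dy
                        f[2] += cmag * dz
        return f

    _force(com, f)
    half = 0.5 * dt
    for step in range(n_steps):
        for d in range(3):
            vel[d] += half * f[d] * kfac
            com[d] += half * vel[d]
            if com[d] < 0.0:
                com[d] = -com[d]
                vel[d] = -vel[d]
            elif com[d] > box[d]:
                com[d] = 2.0 * box[d] - com[d]
                vel[d] = -vel[d]
            vel[d] = c1 * vel[d] + c2 * noise[step, d]
            com[d] += half * vel[d]
            if com[d] < 0.0:
                com[d] = -com[d]
                vel[d] = -vel[d]
            elif com[d] > box[d]:
                com[d] = 2.0 * box[d] - com[d]
                vel[d] = -vel[d]
        _force(com, f)
        for d in range(3):
            vel[d] += half * f[d] * kfac
        if (step + 1) % save_every == 0:
            k = (step + 1) // save_every - 1
            for d in range(3):
                frames_com[k, d] = com[d]
                frames_vel[k, d] = vel[d]
            if not (
                math.isfinite(com[0]) and math.isfinite(com[1]) and math.isfinite(com[2])
            ):
                return step
    return -1


def _spec_kernel_args(spec: PotentialSpec):
    centers, depths, widths = spec.well_arrays()
    bead_q = spec.bead_charges if spec.has_coulomb else np.zeros(0)
    return (
        np.ascontiguousarray(centers),
        np.ascontiguousarray(depths),
        np.ascontiguousarray(widths),
        np.ascontiguousarray(spec.bead_positions),
        float(spec.bead_epsilon),
        float(spec.bead_sigma),
        np.ascontiguousarray(bead_q, dtype=float),
        float(spec.ligand_charge),
        float(spec.dielectric),
    )


def run_segment(
    state: SimState,
    system: ToySystem,
    config: EngineConfig,
    duration: float,
    window_index: int = 0,
) -> TrajectorySegment:
    """Integrate Langevin dynamics for ``duration`` ps from ``state``.

    ``duration`` must be a positive integer multiple of the frame stride.
    Returns frames at ``frame_stride`` spacing (the start point is not a
    frame). The returned ``end_state`` carries the advanced RNG state, so
    running two consecutive segments is frame-identical to one segment of the
    combined duration.
    """
    n_frames_f = duration / config.frame_stride
    if duration <= 0 or abs(n_frames_f - round(n_frames_f)) > 1e-9:
        raise ParameterError("duration must be a positive integer multiple of frame_stride")
    n_frames = int(round(n_frames_f))
    save_every = config.steps_per_frame
    n_steps = n_frames * save_every

    masses = system.ligand_masses
    if masses.size != state.positions.shape[0]:
        raise ParameterError("state does not match the system's ligand atom count")
    total_mass = float(masses.sum())
    com = np.average(state.positions, axis=0, weights=masses)
    offsets = np.ascontiguousarray(state.positions - com)
    vel = np.average(state.velocities, axis=0, weights=masses)

    rng = np.random.default_rng(config.seed)
    if state.rng_state is not None:
        rng.bit_generator.state = state.rng_state
    c1 = math.exp(-config.friction * config.dt)
    kbt = KB * config.temperature * KCAL_TO_AKMA / total_mass
    c2 = math.sqrt(max(0.0, (1.0 - c1 * c1) * kbt))
    noise = rng.standard_normal((n_steps, 3)) if c2 > 0 else np.zeros((n_steps, 3))

    frames_com = np.empty((n_frames, 3))
    frames_vel = np.empty((n_frames, 3))
    bad_step = _baoab(
        com.copy(),
        vel.copy(),
        offsets,
        total_mass,
        noise,
        config.dt,
        c1,
        c2,
        *_spec_kernel_args(system.potential),
        np.ascontiguousarray(system.box),
        save_every,
        frames_com,
        frames_vel,
    )
    if bad_step >= 0:
        raise IntegrationError(
            f"non-finite coordinates at step {bad_step} "
            f"(t = {state.time + bad_step * config.dt:.4f} ps) in window {window_index}"
        )

    times = state.time + config.frame_stride * np.arange(1, n_frames + 1)
    positions = frames_com[:, None, :] + offsets[None, :, :]
    end_state = SimState(
        time=state.time + duration,
        positions=positions[-1].copy(),
        velocities=np.tile(frames_vel[-1], (masses.size, 1)),
        rng_state=rng.bit_generator.state,
    )
    return TrajectorySegment(
        times=times,
        positions=positions,
        start_state=state.copy(),
        end_state=end_state,
        window_index=window_index,
        frame_velocities=frames_vel,
    )
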