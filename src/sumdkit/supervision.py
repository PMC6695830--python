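"""The supervised-MD (SuMD) control loop.

SuMD accelerates the sampling of ligand-receptor binding events without
biasing forces: unbiased dynamics is run in short windows; within each window
the ligand-to-site distance is sampled at regular intervals and fitted to a
straight line; windows with a negative slope (the ligand is approaching) are
kept, all others are discarded and the window is re-run from the same
configuration with freshly randomised Maxwell-Boltzmann velocities. When the
distance drops below a hand-off threshold (5 A by default) supervision is
disabled and plain MD takes over. The result is a continuous, physically
unbiased trajectory whose accepted clock is typically orders of magnitude
shorter than the unsupervised first-binding time.

Window-length presets follow the ligand class: 200 ps suits fast-diffusing
ions, 600 ps small organic molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .analysis import Trajectory
from .engine import EngineConfig, SimState, TrajectorySegment, run_segment, sample_velocities
from .errors import ParameterError, SelectionError
from .model import AtomRecord, ToySystem

logger = logging.getLogger(__name__)

__all__ = [
    "SupervisionConfig",
    "DistanceSeries",
    "WindowRecord",
    "SuMDResult",
    "site_center",
    "ligand_distance",
    "fit_slope",
    "classify_window",
    "run_sumd",
    "first_binding_time",
]


@dataclass
class SupervisionConfig:
    """Parameters of the supervision loop.

    ``distance_sample_interval`` defaults to a tenth of the window (20 ps for
    the 200 ps ion preset), giving ten fitted points per window; it must be a
    multiple of the engine frame stride so distances can be read off saved
    frames. ``site_residues`` names the receptor residues whose mass-weighted
    centroid is the supervision target.
    """

    window_length: float = 200.0  # ps
    distance_sample_interval: float | None = None  # ps; default window/10
    threshold: float = 5.0  # A, supervision hand-off
    max_consecutive_failures: int = 40
    max_total_windows: int = 500
    post_supervision_duration: float = 0.0  # ps of plain MD after binding
    site_residues: list[int] | None = None  # None -> system site "orthosteric"
    site_name: str = "orthosteric"

    def __post_init__(self) -> None:
        if self.distance_sample_interval is None:
            self.distance_sample_interval = self.window_length / 10.0
        if self.threshold <= 0:
            raise ParameterError("threshold must be > 0")
        if self.window_length < 2 * self.distance_sample_interval:
            raise ParameterError(
                "window_length must be >= 2 * distance_sample_interval "
                "(need at least two points to fit a line)"
            )
        if self.max_consecutive_failures < 1 or self.max_total_windows < 1:
            raise ParameterError("failure/window caps must be >= 1")

    @classmethod
    def for_ion(cls, **kw) -> "SupervisionConfig":
        """200 ps windows — adequate for fast-diffusing monatomic ions."""
        kw.setdefault("window_length", 200.0)
        return cls(**kw)

    @classmethod
    def for_small_molecule(cls, **kw) -> "SupervisionConfig":
        """600 ps windows — the classic setting for small organic ligands."""
        kw.setdefault("window_length", 600.0)
        return cls(**kw)


@dataclass
class DistanceSeries:
    """(time, distance) samples collected within one window."""

    times: np.ndarray  # ps
    distances: np.ndarray  # A

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if self.times.size != self.distances.size:
            raise ParameterError("times and distances must have equal lengths")
        if self.times.size < 2:
            raise ParameterError("a distance series needs at least 2 samples")
        dt = np.diff(self.times)
        if not np.all(dt > 0):
            raise ParameterError("sample times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("samples must be equally spaced")

    @property
    def final_distance(self) -> float:
        return float(self.distances[-1])


@dataclass
class WindowRecord:
    """Bookkeeping for one supervision window."""

    index: int
    series: DistanceSeries
    slope: float  # A/ps
    accepted: bool
    restart_seed: int | None = None


@dataclass
class SuMDResult:
    """Outcome of a supervised run.

    ``supervised_time`` counts accepted windows only (the conventional "SuMD
    time"); ``total_attempted_time`` includes rejected windows. Times in ps.
    """

    accepted_trajectory: Trajectory
    window_log: list[WindowRecord]
    termination: str  # bound | failure_cap | window_cap
    supervised_time: float
    total_attempted_time: float
    first_binding_time: float | None = None

    @property
    def n_accepted(self) -> int:
        return sum(1 for w in self.window_log if w.accepted)

    @property
    def n_rejected(self) -> int:
        return sum(1 for w in self.window_log if not w.accepted)


def site_center(
    system: ToySystem | list[AtomRecord], residue_ids: list[int]
) -> np.ndarray:
    """Mass-weighted centroid of the atoms in the listed residues (A)."""
    atoms = system.receptor_atoms if isinstance(system, ToySystem) else system
    by_resid: dict[int, list[AtomRecord]] = {}
    for a in atoms:
        by_resid.setdefault(a.residue_id, []).append(a)
    sel: list[AtomRecord] = []
    for rid in residue_ids:
        if rid not in by_resid:
            raise SelectionError(f"residue id {rid} not present in structure")
        sel.extend(by_resid[rid])
    masses = np.array([a.mass for a in sel])
    positions = np.array([a.position for a in sel])
    return np.average(positions, axis=0, weights=masses)


def ligand_distance(
    positions: np.ndarray,
    center: np.ndarray,
    masses: np.ndarray | None = None,
) -> float:
    """Distance (A) from the ligand center of mass to the site center."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if pos.shape[0] == 0:
        raise SelectionError("empty ligand selection")
    com = np.average(pos, axis=0, weights=masses)
    return float(np.linalg.norm(com - np.asarray(center, dtype=float).reshape(3)))


def fit_slope(series: DistanceSeries) -> float:
    """Ordinary-least-squares slope of distance on time (A/ps)."""
    if np.ptp(series.times) == 0:
        raise ParameterError("zero time variance: cannot fit a slope")
    result = stats.linregress(series.times, series.distances)
    return float(result.slope)


def classify_window(series: DistanceSeries, config: SupervisionConfig) -> str:
    """Decide a window's fate: ``"bound"``, ``"accept"`` or ``"reject"``.

    The bound rule takes precedence over the slope: a window whose final
    sampled distance is below the threshold achieved the goal regardless of
    its trend. Otherwise the window is accepted iff the fitted slope is
    strictly negative — a flat window makes no progress and is rejected.
    """
    if series.final_distance < config.threshold:
        return "bound"
    return "accept" if fit_slope(series) < 0 else "reject"


def _distance_series(
    segment: TrajectorySegment,
    center: np.ndarray,
    masses: np.ndarray,
    sample_interval: float,
    frame_stride: float,
) -> DistanceSeries:
    every = sample_interval / frame_stride
    if abs(every - round(every)) > 1e-9:
        raise ParameterError(
            "distance_sample_interval must be an integer multiple of the engine frame_stride"
        )
    step = int(round(every))
    idx = np.arange(step - 1, segment.n_frames, step)
    dists = [ligand_distance(segment.positions[i], center, masses) for i in idx]
    return DistanceSeries(times=segment.times[idx], distances=np.array(dists))


def run_sumd(
    system: ToySystem,
    engine_config: EngineConfig,
    sup_config: SupervisionConfig,
    seed: int,
) -> SuMDResult:
    """Run the full SuMD loop on ``system``.

    Each window runs unbiased Langevin dynamics for ``window_length`` ps. On
    *accept* the simulation continues from the window's end; on *reject* the
    pre-window positions and clock are restored bit-exactly and only the
    velocities are redrawn from the Maxwell-Boltzmann distribution at the
    thermostat temperature; on *bound* supervision is disabled and
    ``post_supervision_duration`` ps of plain MD are appended. The run halts
    with ``failure_cap`` after ``max_consecutive_failures`` consecutive
    rejects, or ``window_cap`` after ``max_total_windows`` windows.

    Velocity-restart draws and thermostat noise use separate RNG streams
    derived from ``seed``, so the accept/reject sequence is reproducible.
    """
    resids = sup_config.site_residues
    if resids is None:
        resids = system.site_definitions[sup_config.site_name]
    center = site_center(system, resids)
    masses = system.ligand_masses

    dyn_ss, restart_ss = np.random.SeedSequence(seed).spawn(2)
    dyn_rng = np.random.default_rng(dyn_ss)
    restart_rng = np.random.default_rng(restart_ss)

    d0 = ligand_distance(system.ligand_positions, center, masses)
    if d0 <= sup_config.threshold:
        # degenerate threshold: the very first window will classify bound and
        # the run reduces to plain MD
        logger.warning(
            "ligand starts at %.2f A, inside the %.2f A threshold; "
            "supervision is a no-op", d0, sup_config.threshold,
        )

    state = SimState(
        time=0.0,
        positions=system.ligand_positions,
        velocities=sample_velocities(masses, engine_config.temperature, restart_rng),
        rng_state=dyn_rng.bit_generator.state,
    )

    window_log: list[WindowRecord] = []
    accepted_segments: list[TrajectorySegment] = []
    consecutive_failures = 0
    termination = "window_cap"
    first_bind: float | None = None

    for index in range(1, sup_config.max_total_windows + 1):
        pre_state = state.copy()
        segment = run_segment(
            state, system, engine_config, sup_config.window_length, window_index=index
        )
        series = _distance_series(
            segment, center, masses,
            sup_config.distance_sample_interval, engine_config.frame_stride,
        )
        slope = fit_slope(series)
        decision = classify_window(series, sup_config)
        logger.info(
            "window %d: slope=%+.4f A/ps final=%.2f A -> %s",
            index, slope, series.final_distance, decision,
        )

        if decision == "reject":
            rseed = int(restart_ss.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
            window_log.append(WindowRecord(index, series, slope, False, restart_seed=rseed))
            consecutive_failures += 1
            # restore pre-window positions and clock; redraw velocities only
            state = pre_state
            state.velocities = sample_velocities(
                masses, engine_config.temperature, rseed
            )
            # thermostat noise continues on the dynamics stream advanced by
            # the rejected attempt, so repeated windows explore new noise
            state.rng_state = segment.end_state.rng_state
            if consecutive_failures >= sup_config.max_consecutive_failures:
                termination = "failure_cap"
                break
            continue

        window_log.append(WindowRecord(index, series, slope, True))
        accepted_segments.append(segment)
        consecutive_failures = 0
        state = segment.end_state

        if decision == "bound":
            termination = "bound"
            below = series.distances < sup_config.threshold
            first_bind = float(series.times[np.argmax(below)])
            if sup_config.post_supervision_duration > 0:
                tail = run_segment(
                    state, system, engine_config,
                    sup_config.post_supervision_duration, window_index=index + 1,
                )
                accepted_segments.append(tail)
            break

    n_windows = len(window_log)
    n_accepted = sum(1 for w in window_log if w.accepted)
    if not accepted_segments:
        # no accepted window at all: an empty trajectory at the start point
        traj = Trajectory(
            times=np.zeros(1),
            coords=np.concatenate(
                [system.receptor_positions, system.ligand_positions]
            )[None],
            topology=system.topology,
            stride=engine_config.frame_stride,
        )
    else:
        traj = Trajectory.from_segments(accepted_segments, system)
    return SuMDResult(
        accepted_trajectory=traj,
        window_log=window_log,
        termination=termination,
        supervised_time=n_accepted * sup_config.window_length,
        total_attempted_time=n_windows * sup_config.window_length,
        first_binding_time=first_bind,
    )


def first_binding_time(
    traj_positions: np.ndarray,
    times: np.ndarray,
    center: np.ndarray,
    threshold: float,
    masses: np.ndarray | None = None,
) -> float | None:
    """First frame time at which the ligand COM is within ``threshold`` of
    ``center``; ``None`` if never. Used to score plain-MD comparison runs."""
    pos = np.asarray(traj_positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    for i in range(pos.shape[0]):
        if ligand_distance(pos[i], center, masses) < threshold:
            return float(times[i])
    return None
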