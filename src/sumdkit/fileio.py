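"""Structure and trajectory file formats.

PDB: a fixed-column subset (ATOM/HETATM records) sufficient for crystal
structures and for the bead receptor written by ``generate-system``. When
writing, the atom's mass is stored in the occupancy column and its van der
Waals radius in the B-factor column, so coarse-grained pseudo-atoms
round-trip exactly; readers of real crystal structures leave the flags off
and take masses/radii from the element table.

XYZ: the frame comment line carries ``t=<ps> window=<idx>`` so trajectory
time and supervision-window provenance survive a round-trip; coordinates are
written at 3 decimals (exact at that precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .analysis import Trajectory
from .elements import guess_element, mass_of, vdw_radius_of
from .errors import FormatError
from .model import AtomRecord

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_traj",
    "write_traj",
    "write_frame_sidecar",
]


def read_pdb(
    path: str | Path,
    *,
    mass_from_occupancy: bool = False,
    radius_from_bfactor: bool = False,
) -> list[AtomRecord]:
    """Parse ATOM/HETATM records into :class:`AtomRecord` objects.

    Masses and radii come from the element table unless the override flags
    are set (used for files written by :func:`write_pdb`, which stores mass
    and vdW radius in the occupancy/B-factor columns). Records other than
    ATOM/HETATM are ignored. Malformed numeric fields raise
    :class:`FormatError` naming the line.
    """
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                res_name = line[17:21].strip()
                chain = line[21] if line[21].strip() else " "
                res_id = int(line[22:26])
                pos = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
                bfactor = float(line[60:66]) if line[60:66].strip() else 0.0
                element_field = line[76:78] if len(line) >= 78 else ""
            except ValueError as exc:
                raise FormatError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            element = guess_element(name, element_field)
            mass = occupancy if mass_from_occupancy and occupancy > 0 else mass_of(element)
            radius = bfactor if radius_from_bfactor and bfactor > 0 else vdw_radius_of(element)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name=res_name,
                    residue_id=res_id,
                    chain=chain,
                    position=np.array(pos),
                    mass=mass,
                    vdw_radius=radius,
                )
            )
    return atoms


def write_pdb(atoms: list[AtomRecord], path: str | Path) -> None:
    """Write atoms as HETATM records (mass -> occupancy, vdW radius -> B)."""
    with open(path, "w") as fh:
        for a in atoms:
            elem = guess_element(a.name)
            fh.write(
                f"HETATM{a.serial:5d} {a.name:<4.4s} {a.residue_name:<3.3s} "
                f"{a.chain}{a.residue_id:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{a.mass:6.2f}{a.vdw_radius:6.2f}          {elem:>2.2s}\n"
            )
        fh.write("END\n")


def write_traj(
    traj: Trajectory, path: str | Path, window_indices: np.ndarray | None = None
) -> None:
    """Write a trajectory in XYZ with ``t=<ps> window=<idx>`` comments."""
    windows = (
        np.zeros(traj.n_frames, dtype=int)
        if window_indices is None
        else np.asarray(window_indices, dtype=int)
    )
    names = [a.name for a in traj.topology] or ["X"] * traj.n_atoms
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t={traj.times[i]:.3f} window={windows[i]}\n")
            for name, xyz in zip(names, traj.coords[i]):
                fh.write(f"{name:<4s} {xyz[0]:12.3f} {xyz[1]:12.3f} {xyz[2]:12.3f}\n")


def read_traj(
    path: str | Path,
    topology: list[AtomRecord] | None = None,
    return_windows: bool = False,
):
    """Read an XYZ trajectory written by :func:`write_traj`.

    A truncated frame or a mid-file atom-count change raises
    :class:`FormatError` naming the frame. An empty file reads back as a
    0-frame trajectory.
    """
    times: list[float] = []
    windows: list[int] = []
    frames: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_index = 0
    n_atoms: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: bad atom-count line at frame {frame_index}"
            ) from exc
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise FormatError(
                f"{path}: atom count changed from {n_atoms} to {count} at frame {frame_index}"
            )
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated frame {frame_index}")
        comment = lines[i + 1]
        t, window = 0.0, 0
        for tok in comment.split():
            if tok.startswith("t="):
                t = float(tok[2:])
            elif tok.startswith("window="):
                window = int(tok[7:])
        coords = np.empty((count, 3))
        frame_names: list[str] = []
        for j in range(count):
            k = i + 2 + j
            if k >= len(lines):
                raise FormatError(f"{path}: truncated frame {frame_index}")
            parts = lines[k].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: truncated frame {frame_index}")
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: malformed coordinates in frame {frame_index}"
                ) from exc
            frame_names.append(parts[0])
        if not names:
            names = frame_names
        times.append(t)
        windows.append(window)
        frames.append(coords)
        i += 2 + count
        frame_index += 1

    if not frames:
        traj = Trajectory(
            times=np.zeros(0), coords=np.zeros((0, 0, 3)), topology=topology or []
        )
        return (traj, np.zeros(0, dtype=int)) if return_windows else traj

    if topology is None:
        topology = [
            AtomRecord(
                serial=j + 1,
                name=names[j],
                residue_name=names[j][:3] or "UNK",
                residue_id=j + 1,
                chain=" ",
                position=frames[0][j],
                mass=mass_of(guess_element(names[j])),
                vdw_radius=vdw_radius_of(guess_element(names[j])),
            )
            for j in range(len(names))
        ]
    stride = times[1] - times[0] if len(times) > 1 else 0.0
    traj = Trajectory(
        times=np.array(times), coords=np.stack(frames), topology=topology, stride=stride
    )
    return (traj, np.array(windows, dtype=int)) if return_windows else traj


def write_frame_sidecar(
    path: str | Path,
    times: np.ndarray,
    window_indices: np.ndarray,
    accepted: np.ndarray,
) -> None:
    """JSON sidecar mapping frame -> (window_index, accepted flag, time ps)."""
    payload = {
        str(i): {
            "window": int(w),
            "accepted": bool(a),
            "time_ps": float(t),
        }
        for i, (t, w, a) in enumerate(zip(times, window_indices, accepted))
    }
    Path(path).write_text(json.dumps(payload, indent=1))
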