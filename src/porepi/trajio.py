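"""Trajectory file I/O.

Trajectories are stored as multi-frame extended XYZ: each frame carries a
``Lattice`` (orthorhombic box), a ``Properties`` descriptor with per-atom
species, position and particle id columns, the frame ``Time`` in ps, and —
on the first frame — the trajectory metadata as a JSON string.  The format
is self-describing and round-trips losslessly at the printed precision
(6 decimals).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .synthetic_data import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "export_frame_pdb",
           "TrajectoryParseError"]


class TrajectoryParseError(ValueError):
    """Raised for malformed trajectory files; names the frame and line."""


_PROPERTIES = "species:S:1:pos:R:3:id:I:1"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-frame extended-XYZ file."""
    if traj.n_frames == 0:
        raise ValueError("no frames: refusing to write an empty trajectory")
    lx, ly, lz = traj.box
    lattice = f'Lattice="{lx:.6f} 0 0 0 {ly:.6f} 0 0 0 {lz:.6f}"'
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            comment = (
                f"{lattice} Properties={_PROPERTIES} Time={traj.times[f]:.6f}"
            )
            if f == 0 and traj.metadata:
                comment += " Metadata=" + json.dumps(
                    traj.metadata, separators=(",", ":"), sort_keys=True
                ).replace(" ", "")
            fh.write(comment + "\n")
            for p in range(traj.n_particles):
                x, y, z = traj.coords[f, p]
                fh.write(
                    f"{traj.species[p]} {x:.6f} {y:.6f} {z:.6f} {int(traj.ids[p])}\n"
                )


def export_frame_pdb(traj: Trajectory, frame: int, path) -> None:
    """Write one frame as a PDB snapshot (ions as NA, waters as HOH/O)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range (n_frames="
                         f"{traj.n_frames})")
    n = traj.n_particles
    arr = struc.AtomArray(n)
    for i in range(n):
        sp = traj.species[i]
        arr.coord[i] = traj.coords[frame, i]
        arr.chain_id[i] = "A"
        arr.res_id[i] = int(traj.ids[i]) + 1
        arr.res_name[i] = {"ion": "NA", "water": "HOH"}.get(sp, "UNK")
        arr.atom_name[i] = {"ion": "NA", "water": "O"}.get(sp, "C")
        arr.element[i] = {"ion": "NA", "water": "O"}.get(sp, "C")
        arr.hetero[i] = True
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-\d.eE+]+)")
_META_RE = re.compile(r"Metadata=(\{.*\})")


def read_trajectory(path) -> Trajectory:
    """Read a multi-frame extended-XYZ file written by :func:`write_trajectory`."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise TrajectoryParseError(f"{path}: no frames (empty file)")
    times, frames = [], []
    box = None
    ids0 = species0 = None
    metadata: dict = {}
    ln = 0
    frame = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"frame {frame}, line {ln + 1}: expected atom count, got "
                f"{lines[ln]!r}"
            ) from None
        if ln + 1 >= len(lines):
            raise TrajectoryParseError(
                f"frame {frame}, line {ln + 2}: missing comment line"
            )
        comment = lines[ln + 1]
        m = _LATTICE_RE.search(comment)
        if m:
            vals = [float(v) for v in m.group(1).split()]
            box = np.array([vals[0], vals[4], vals[8]])
        m = _TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else float(frame))
        m = _META_RE.search(comment)
        if m and not metadata:
            try:
                metadata = json.loads(m.group(1))
            except json.JSONDecodeError as exc:
                raise TrajectoryParseError(
                    f"frame {frame}, line {ln + 2}: bad metadata JSON ({exc})"
                ) from None
        body = lines[ln + 2: ln + 2 + natoms]
        if len(body) < natoms:
            raise TrajectoryParseError(
                f"frame {frame}, line {len(lines)}: truncated frame "
                f"(expected {natoms} atom lines, found {len(body)})"
            )
        sp, ids, xyz = [], [], []
        for j, row in enumerate(body):
            parts = row.split()
            if len(parts) != 5:
                raise TrajectoryParseError(
                    f"frame {frame}, line {ln + 3 + j}: expected 5 columns "
                    f"(species x y z id), got {len(parts)}"
                )
            try:
                sp.append(parts[0])
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
                ids.append(int(parts[4]))
            except ValueError:
                raise TrajectoryParseError(
                    f"frame {frame}, line {ln + 3 + j}: unparsable atom "
                    f"record {row!r}"
                ) from None
        if ids0 is None:
            ids0, species0 = np.array(ids), np.array(sp)
        elif not (np.array_equal(ids0, ids) and np.array_equal(species0, sp)):
            raise TrajectoryParseError(
                f"frame {frame}, line {ln + 3}: particle identities differ "
                "from first frame"
            )
        frames.append(np.array(xyz))
        ln += 2 + natoms
        frame += 1
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames")
    if box is None:
        raise TrajectoryParseError(f"{path}: no Lattice record found")
    return Trajectory(
        times=np.array(times), box=box, ids=ids0, species=species0,
        coords=np.stack(frames), metadata=metadata,
    )
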