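"""Tagged-particle trajectory container and text I/O.

A :class:`Trajectory` stores per-frame coordinates for a small set of
tagged atoms — pore-bound ions, interlayer water molecules — together
with the box, the axial positions of the two graphene layers and a role
tag per atom.  The transport axis is z: layer planes are z = layer_z1
and z = layer_z2 and the pore axis passes through (x, y) = pore_center.

On disk a trajectory is a multi-frame XYZ file (the comment line carries
the frame time in ps) plus a JSON metadata sidecar with keys
``timestep_ps``, ``box``, ``periodic``, ``layer_z1``, ``layer_z2``,
``pore_center`` and ``roles`` (atom index → role).  Roles are
``ion:K``, ``ion:Na``, ``waterO`` or ``waterH``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AnalysisError, FormatError

__all__ = ["Trajectory", "write_trajectory", "read_trajectory"]


@dataclass
class Trajectory:
    timestep_ps: float
    box: tuple[float, float, float]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    roles: dict[int, str]
    layer_z1: float
    layer_z2: float
    periodic: tuple[bool, bool, bool] = (False, False, True)
    pore_center: tuple[float, float] = (0.0, 0.0)
    times: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise AnalysisError("coords must have shape (frames, atoms, 3)")
        if self.timestep_ps <= 0:
            raise AnalysisError("timestep must be positive")
        if self.layer_z2 <= self.layer_z1:
            raise AnalysisError("layer_z2 must be above layer_z1")
        if self.times is None:
            self.times = np.arange(self.n_frames) * self.timestep_ps

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ps(self) -> float:
        return (self.n_frames - 1) * self.timestep_ps

    def ion_indices(self, species: str | None = None) -> list[int]:
        out = []
        for i in range(self.n_atoms):
            role = self.roles.get(i, "")
            if role.startswith("ion:") and (
                species is None or role == f"ion:{species}"
            ):
                out.append(i)
        return out

    def water_oxygens(self) -> list[int]:
        return [i for i in range(self.n_atoms) if self.roles.get(i) == "waterO"]

    def water_groups(self) -> list[tuple[int, int, int]]:
        """(O, H1, H2) triples; hydrogens are the two atoms following each O."""
        groups = []
        for o in self.water_oxygens():
            hs = [
                j
                for j in (o + 1, o + 2)
                if j < self.n_atoms and self.roles.get(j) == "waterH"
            ]
            if len(hs) == 2:
                groups.append((o, hs[0], hs[1]))
        return groups

    def element(self, index: int) -> str:
        role = self.roles.get(index, "C")
        if role.startswith("ion:"):
            return role.split(":", 1)[1]
        return {"waterO": "O", "waterH": "H"}.get(role, "C")


def write_trajectory(traj: Trajectory, xyz_path: str | Path) -> tuple[Path, Path]:
    """Write multi-frame XYZ + JSON sidecar (``<name>.meta.json``)."""
    xyz_path = Path(xyz_path)
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"t= {traj.times[f]:.6f} ps")
        for a in range(traj.n_atoms):
            x, y, z = traj.coords[f, a]
            lines.append(f"{traj.element(a)} {x:.5f} {y:.5f} {z:.5f}")
    xyz_path.write_text("\n".join(lines) + "\n")
    meta = {
        "timestep_ps": traj.timestep_ps,
        "box": list(traj.box),
        "periodic": list(traj.periodic),
        "layer_z1": traj.layer_z1,
        "layer_z2": traj.layer_z2,
        "pore_center": list(traj.pore_center),
        "roles": {str(k): v for k, v in traj.roles.items()},
        **({"generator": traj.metadata} if traj.metadata else {}),
    }
    meta_path = xyz_path.with_suffix(xyz_path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return xyz_path, meta_path


def read_trajectory(xyz_path: str | Path, meta_path: str | Path | None = None) -> Trajectory:
    """Read a multi-frame XYZ trajectory with its metadata sidecar."""
    xyz_path = Path(xyz_path)
    if meta_path is None:
        meta_path = xyz_path.with_suffix(xyz_path.suffix + ".meta.json")
    meta = json.loads(Path(meta_path).read_text())

    lines = xyz_path.read_text().splitlines()
    frames = []
    times = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"bad XYZ frame header at line {i + 1}") from exc
        comment = lines[i + 1]
        if "t=" in comment:
            times.append(float(comment.split("t=")[1].split()[0]))
        frame = []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(frame)
        i += 2 + n
    coords = np.array(frames)
    return Trajectory(
        timestep_ps=float(meta["timestep_ps"]),
        box=tuple(meta["box"]),
        coords=coords,
        roles={int(k): v for k, v in meta["roles"].items()},
        layer_z1=float(meta["layer_z1"]),
        layer_z2=float(meta["layer_z2"]),
        periodic=tuple(bool(p) for p in meta.get("periodic", (False, False, True))),
        pore_center=tuple(meta.get("pore_center", (0.0, 0.0))),
        times=np.array(times) if len(times) == len(frames) else None,
        metadata=meta.get("generator", {}),
    )
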