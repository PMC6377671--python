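"""In-memory trajectory container and plain-text trajectory I/O.

A :class:`Trajectory` holds the per-frame coordinates of the solute (drug)
atoms, labelled lipid pseudo-atoms, the orthorhombic box, and optionally the
unit orientation vectors of named molecular axes.  Trajectories are written
as multi-MODEL PDB (component role in resName and segid, box in CRYST1) or as
plain XYZ with a sidecar CSV label table, and read back either with this
module or any standard PDB reader.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "write_pdb_trajectory",
    "read_pdb_trajectory",
    "write_xyz_trajectory",
]

LIPID_ROLES = ("CHOL", "PO4", "GLY", "TAIL")


@dataclass
class Trajectory:
    """Frames of a drug-near-bilayer system in an orthorhombic box.

    Coordinates are in Å with the bilayer center at z = 0; times in ns.
    ``orientations`` maps a vector name to an (n_frames, 3) array of unit
    vectors (head minus tail of the named molecular axis).
    """

    times: np.ndarray  # (n_frames,)
    drug_coords: np.ndarray  # (n_frames, n_drug, 3)
    lipid_coords: np.ndarray  # (n_frames, n_lipid, 3)
    lipid_roles: np.ndarray  # (n_lipid,) str
    lipid_leaflets: np.ndarray  # (n_lipid,) 'U' or 'L'
    box: np.ndarray  # (3,) Å
    orientations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.drug_coords = np.asarray(self.drug_coords, dtype=float)
        self.lipid_coords = np.asarray(self.lipid_coords, dtype=float)
        self.lipid_roles = np.asarray(self.lipid_roles, dtype="U8")
        self.lipid_leaflets = np.asarray(self.lipid_leaflets, dtype="U1")
        self.box = np.asarray(self.box, dtype=float)
        if self.n_frames and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must strictly increase")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_drug_atoms(self) -> int:
        return self.drug_coords.shape[1] if self.drug_coords.ndim == 3 else 0

    @property
    def n_lipid_atoms(self) -> int:
        return self.lipid_coords.shape[1] if self.lipid_coords.ndim == 3 else 0

    @property
    def drug_com_z(self) -> np.ndarray:
        """Per-frame z of the drug center of mass (equal-mass atoms)."""
        if self.n_frames == 0:
            return np.empty(0)
        return self.drug_coords[:, :, 2].mean(axis=1)

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a frame interval")
        return float(self.times[1] - self.times[0])


def _atom_rows(traj: Trajectory) -> list[tuple[str, str, str]]:
    """(atom_name, role, leaflet) for every atom, drug first."""
    rows = [("C", "DRUG", "D")] * traj.n_drug_atoms
    rows += [
        (role[:1] if role != "PO4" else "P", role, leaf)
        for role, leaf in zip(traj.lipid_roles, traj.lipid_leaflets)
    ]
    return rows


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-MODEL PDB; role goes in resName and segid, leaflet in chainID.

    An empty trajectory still produces a valid header (CRYST1 + END).
    """
    path = Path(path)
    rows = _atom_rows(traj)
    cryst = (
        f"CRYST1{traj.box[0]:9.3f}{traj.box[1]:9.3f}{traj.box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    with path.open("w") as fh:
        fh.write(cryst)
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:4d}\n")
            # repeated per frame so stream-based readers pick up the box
            fh.write(cryst)
            fh.write(f"REMARK   6 TIME_NS {traj.times[i]:.6f}\n")
            coords = (
                np.vstack([traj.drug_coords[i], traj.lipid_coords[i]])
                if traj.n_lipid_atoms
                else traj.drug_coords[i]
            )
            for serial, ((name, role, leaf), xyz) in enumerate(zip(rows, coords), 1):
                fh.write(
                    f"HETATM{serial % 100000:5d} {name:<4s} {role:<4s}{leaf}"
                    f"{serial % 10000:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}      {role:<4s}{name[:1]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_pdb_trajectory`."""
    path = Path(path)
    box = np.zeros(3)
    times: list[float] = []
    frames: list[np.ndarray] = []
    roles: list[str] = []
    current: list[list[float]] = []
    first_model = True
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "CRYST1":
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            elif rec.startswith("MODEL"):
                current = []
            elif line.startswith("REMARK   6 TIME_NS"):
                times.append(float(line.split()[-1]))
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable record") from exc
                if first_model:
                    roles.append(line[17:21].strip())
            elif rec == "ENDMDL":
                frames.append(np.array(current).reshape(-1, 3))
                first_model = False
    roles_arr = np.array(roles, dtype="U8")
    drug_mask = roles_arr == "DRUG"
    n_frames = len(frames)
    if n_frames == 0:
        return Trajectory(
            times=np.empty(0),
            drug_coords=np.empty((0, 0, 3)),
            lipid_coords=np.empty((0, 0, 3)),
            lipid_roles=np.empty(0, dtype="U8"),
            lipid_leaflets=np.empty(0, dtype="U1"),
            box=box,
        )
    stack = np.stack(frames)
    if len(times) != n_frames:
        times = list(np.arange(n_frames, dtype=float))
    return Trajectory(
        times=np.array(times),
        drug_coords=stack[:, drug_mask, :],
        lipid_coords=stack[:, ~drug_mask, :],
        lipid_roles=roles_arr[~drug_mask],
        lipid_leaflets=np.full((~drug_mask).sum(), "?", dtype="U1"),
        box=box,
    )


def write_xyz_trajectory(traj: Trajectory, xyz_path: str | Path, labels_path: str | Path) -> None:
    """Write plain multi-frame XYZ plus a sidecar CSV label table.

    The CSV has columns atom_index, role (drug/CHOL/PO4/GLY/TAIL), leaflet.
    """
    rows = _atom_rows(traj)
    n_atoms = len(rows)
    with Path(xyz_path).open("w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"t_ns={traj.times[i]:.6f} box={traj.box[0]:.3f},{traj.box[1]:.3f},{traj.box[2]:.3f}\n")
            coords = (
                np.vstack([traj.drug_coords[i], traj.lipid_coords[i]])
                if traj.n_lipid_atoms
                else traj.drug_coords[i]
            )
            for (name, _, _), xyz in zip(rows, coords):
                fh.write(f"{name:<2s} {xyz[0]:12.5f} {xyz[1]:12.5f} {xyz[2]:12.5f}\n")
    with Path(labels_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["atom_index", "role", "leaflet"])
        for idx, (_, role, leaf) in enumerate(rows):
            writer.writerow([idx, "drug" if role == "DRUG" else role, leaf])
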