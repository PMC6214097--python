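"""Ligand pose model: the 7+tau pose vector, torsion-tree kinematics, RMSD, PDBQT I/O.

A ligand conformation is encoded as a vector of 7+tau elements: 3 Cartesian
position coordinates (Angstrom), a unit quaternion (w, x, y, z) for the rigid
orientation, and tau torsion angles (radians), one per rotatable bond of the
ligand's torsion tree.  Torsion values are rotations *relative to the reference
geometry* stored in the topology, so the identity pose reproduces the input
coordinates exactly.

Coordinates are handled in Angstrom internally; RMSD is reported in nm, the
unit used for the docking success threshold (0.2 nm).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PoseVector",
    "LigandTopology",
    "Branch",
    "DockingBox",
    "PDBQTError",
    "TopologyError",
    "wrap_angle",
    "quaternion_angle",
    "random_unit_quaternion",
    "apply_pose",
    "rmsd",
    "pose_rmsd",
    "read_pdbqt_ligand",
    "write_pdbqt_ligand",
    "write_pdbqt_models",
]


class PDBQTError(ValueError):
    """Malformed PDBQT ligand file."""


class TopologyError(ValueError):
    """Inconsistent ligand topology (e.g. zero-length rotatable bond)."""


def wrap_angle(theta):
    """Wrap angle(s) into (-pi, pi]."""
    t = np.asarray(theta, dtype=float)
    wrapped = -(((-t + np.pi) % (2.0 * np.pi)) - np.pi)
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


def quaternion_angle(q1, q2) -> float:
    """Rotation angle (rad) between two quaternions, 2*acos(|q1 . q2|); sign-invariant."""
    a = np.asarray(q1, dtype=float)
    b = np.asarray(q2, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    d = abs(float(np.dot(a, b)))
    return 2.0 * np.arccos(min(d, 1.0))


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation as a scalar-first unit quaternion."""
    q = rng.normal(size=4)
    n = np.linalg.norm(q)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        q = rng.normal(size=4)
        n = np.linalg.norm(q)
    return q / n


@dataclasses.dataclass
class PoseVector:
    """One ligand pose: position (A), scalar-first unit quaternion, torsions (rad)."""

    position: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(4)
        self.torsions = np.atleast_1d(np.asarray(self.torsions, dtype=float))

    @property
    def n_torsions(self) -> int:
        return self.torsions.size

    @property
    def size(self) -> int:
        """Total element count, 7 + tau."""
        return 7 + self.n_torsions

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.position, self.orientation, self.torsions])

    @classmethod
    def from_array(cls, arr, n_torsions: int) -> "PoseVector":
        arr = np.asarray(arr, dtype=float)
        if arr.size != 7 + n_torsions:
            raise ValueError(
                f"pose array has {arr.size} elements, expected {7 + n_torsions}"
            )
        return cls(arr[:3], arr[3:7], arr[7:])

    def normalized(self) -> "PoseVector":
        """Canonical copy: unit quaternion, torsions wrapped into (-pi, pi]."""
        n = np.linalg.norm(self.orientation)
        if n < 1e-12:
            raise ValueError("degenerate quaternion (norm ~ 0)")
        return PoseVector(
            self.position.copy(),
            self.orientation / n,
            wrap_angle(self.torsions) if self.n_torsions else self.torsions.copy(),
        )

    def copy(self) -> "PoseVector":
        return PoseVector(
            self.position.copy(), self.orientation.copy(), self.torsions.copy()
        )

    def rotation(self) -> Rotation:
        q = self.orientation / np.linalg.norm(self.orientation)
        return Rotation.from_quat(q, scalar_first=True)


@dataclasses.dataclass
class Branch:
    """One rotatable bond of the torsion tree.

    ``moved`` holds every atom index rotated by this torsion (the whole subtree,
    the on-axis child atom excluded); ``block_atoms`` are only the atoms written
    directly inside this BRANCH block (used to re-serialize the file), and
    ``children`` indexes nested branches.
    """

    parent: int
    child: int
    moved: np.ndarray
    block_atoms: list = dataclasses.field(default_factory=list)
    children: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class LigandTopology:
    """Reference geometry plus the PDBQT ROOT/BRANCH torsion tree."""

    coords: np.ndarray            # (n, 3) reference coordinates, Angstrom
    names: list
    atom_types: list
    charges: np.ndarray
    serials: np.ndarray           # original PDBQT serial numbers (metadata only)
    resnames: list
    root: np.ndarray              # atom indices in the ROOT block
    branches: list                # list[Branch], file (root-to-leaf) order
    torsdof: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.serials = np.asarray(self.serials, dtype=int)
        self.root = np.asarray(self.root, dtype=int)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_torsions(self) -> int:
        return len(self.branches)

    @property
    def anchor(self) -> np.ndarray:
        """Rotation/translation anchor: reference coordinate of the first ROOT atom."""
        return self.coords[self.root[0]]

    def identity_pose(self) -> PoseVector:
        """Pose that reproduces the reference coordinates exactly."""
        return PoseVector(
            self.anchor.copy(),
            np.array([1.0, 0.0, 0.0, 0.0]),
            np.zeros(self.n_torsions),
        )


@dataclasses.dataclass
class DockingBox:
    """Axis-aligned search region: center and full edge lengths, Angstrom."""

    center: np.ndarray
    extents: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.extents = np.asarray(self.extents, dtype=float).reshape(3)
        if np.any(self.extents <= 0):
            raise ValueError("box extents must be positive")

    @property
    def lower(self) -> np.ndarray:
        return self.center - self.extents / 2.0

    @property
    def upper(self) -> np.ndarray:
        return self.center + self.extents / 2.0

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.lower) and np.all(p <= self.upper))

    def clamp(self, point) -> np.ndarray:
        return np.clip(np.asarray(point, dtype=float), self.lower, self.upper)

    def random_position(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)


def _quat_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion (active rotation)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_angle_matrix(u: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about unit axis ``u`` by ``theta``."""
    c = np.cos(theta)
    s = np.sin(theta)
    one_c = 1.0 - c
    ux, uy, uz = u
    return np.array(
        [
            [c + ux * ux * one_c, ux * uy * one_c - uz * s, ux * uz * one_c + uy * s],
            [uy * ux * one_c + uz * s, c + uy * uy * one_c, uy * uz * one_c - ux * s],
            [uz * ux * one_c - uy * s, uz * uy * one_c + ux * s, c + uz * uz * one_c],
        ]
    )


def apply_pose(topology: LigandTopology, pose: PoseVector) -> np.ndarray:
    """Generate atom coordinates (A) for a pose.

    Torsions are applied root-to-leaf on the reference geometry (rotating each
    branch's subtree about its bond axis), then the whole molecule is rigidly
    rotated by the quaternion about the root anchor and translated so the
    anchor sits at ``pose.position``.
    """
    if pose.n_torsions != topology.n_torsions:
        raise ValueError(
            f"pose has {pose.n_torsions} torsions but topology has "
            f"{topology.n_torsions} rotatable bonds"
        )
    q = pose.orientation
    qn = np.sqrt(q @ q)
    if qn < 1e-12:
        raise ValueError("degenerate quaternion (norm ~ 0)")
    coords = topology.coords.copy()
    for branch, theta in zip(topology.branches, pose.torsions):
        axis = coords[branch.child] - coords[branch.parent]
        norm = np.sqrt(axis @ axis)
        if norm < 1e-9:
            raise TopologyError(
                f"zero-length rotatable bond between atoms "
                f"{branch.parent} and {branch.child}"
            )
        if branch.moved.size and theta != 0.0:
            rot = _axis_angle_matrix(axis / norm, theta)
            pivot = coords[branch.parent]
            coords[branch.moved] = (coords[branch.moved] - pivot) @ rot.T + pivot
    rot = _quat_matrix(q / qn)
    return (coords - topology.anchor) @ rot.T + pose.position


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation between two coordinate sets (A in, nm out).

    No superposition: docking RMSD is measured in the receptor frame with a
    fixed atom correspondence.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    dev = a - b
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=-1))) / 10.0)


def pose_rmsd(topology: LigandTopology, pose_a: PoseVector, pose_b: PoseVector) -> float:
    """RMSD (nm) between the atom coordinates two poses generate."""
    return rmsd(apply_pose(topology, pose_a), apply_pose(topology, pose_b))


# ---------------------------------------------------------------------------
# PDBQT ligand dialect I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or "LIG"
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBQTError(f"line {lineno}: malformed ATOM record: {line!r}") from exc
    tail = line[66:].split()
    charge = 0.0
    atype = name[:1] or "C"
    if len(tail) >= 2:
        try:
            charge = float(tail[-2])
        except ValueError:
            pass
        atype = tail[-1]
    elif len(tail) == 1:
        atype = tail[0]
    return serial, name, resname, (x, y, z), charge, atype


def read_pdbqt_ligand(path) -> LigandTopology:
    """Parse a PDBQT ligand (ROOT/BRANCH torsion-tree dialect).

    Only the first MODEL is read from multi-model files.  Raises
    :class:`PDBQTError` with a line number on unbalanced BRANCH nesting or a
    missing ROOT block.
    """
    lines = Path(path).read_text().splitlines()

    serials, names, resnames, coords, charges, types = [], [], [], [], [], []
    root_atoms: list[int] = []
    branches: list[Branch] = []
    stack: list[int] = []          # indices into ``branches``
    in_root = False
    seen_root = False
    torsdof = None
    in_model = False
    serial_to_index: dict[int, int] = {}

    for lineno, raw in enumerate(lines, start=1):
        rec = raw[:6].strip().upper()
        if rec == "MODEL":
            if in_model:
                break
            in_model = True
            continue
        if rec == "ENDMDL":
            break
        if rec == "ROOT":
            if seen_root:
                raise PDBQTError(f"line {lineno}: duplicate ROOT block")
            seen_root = True
            in_root = True
            continue
        if rec == "ENDROO":  # ENDROOT truncated to 6 cols
            in_root = False
            continue
        if rec == "BRANCH":
            parts = raw.split()
            if len(parts) < 3:
                raise PDBQTError(f"line {lineno}: BRANCH needs two atom serials")
            try:
                s_parent, s_child = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PDBQTError(f"line {lineno}: bad BRANCH serials") from exc
            branch = Branch(parent=s_parent, child=s_child, moved=np.empty(0, int))
            idx = len(branches)
            branches.append(branch)
            if stack:
                branches[stack[-1]].children.append(idx)
            stack.append(idx)
            continue
        if rec == "ENDBRA":  # ENDBRANCH
            if not stack:
                raise PDBQTError(f"line {lineno}: ENDBRANCH without open BRANCH")
            parts = raw.split()
            top = branches[stack[-1]]
            if len(parts) >= 3:
                try:
                    s_parent, s_child = int(parts[1]), int(parts[2])
                except ValueError:
                    s_parent, s_child = top.parent, top.child
                if (s_parent, s_child) != (top.parent, top.child):
                    raise PDBQTError(
                        f"line {lineno}: ENDBRANCH {s_parent} {s_child} does not "
                        f"match open BRANCH {top.parent} {top.child}"
                    )
            stack.pop()
            continue
        if rec == "TORSDO":  # TORSDOF
            parts = raw.split()
            if len(parts) >= 2:
                try:
                    torsdof = int(parts[1])
                except ValueError:
                    torsdof = None
            continue
        if rec in ("ATOM", "HETATM"):
            serial, name, resname, xyz, charge, atype = _parse_atom_line(raw, lineno)
            idx = len(serials)
            serials.append(serial)
            names.append(name)
            resnames.append(resname)
            coords.append(xyz)
            charges.append(charge)
            types.append(atype)
            serial_to_index[serial] = idx
            if stack:
                branches[stack[-1]].block_atoms.append(idx)
            elif in_root:
                root_atoms.append(idx)
            else:
                raise PDBQTError(
                    f"line {lineno}: atom outside ROOT/BRANCH blocks"
                )
            continue
        # REMARK / USER / other records ignored

    if stack:
        open_b = branches[stack[-1]]
        raise PDBQTError(
            f"unbalanced BRANCH nesting: BRANCH {open_b.parent} {open_b.child} "
            "never closed"
        )
    if not seen_root:
        raise PDBQTError("missing ROOT block")
    if not root_atoms:
        raise PDBQTError("ROOT block contains no atoms")

    # Resolve branch serials to indices and build subtree moved-atom sets.
    for branch in branches:
        try:
            branch.parent = serial_to_index[branch.parent]
            branch.child = serial_to_index[branch.child]
        except KeyError as exc:
            raise PDBQTError(f"BRANCH references unknown atom serial {exc}") from exc

    def subtree_atoms(bidx: int) -> list[int]:
        b = branches[bidx]
        atoms = list(b.block_atoms)
        for c in b.children:
            atoms.extend(subtree_atoms(c))
        return atoms

    for bidx, branch in enumerate(branches):
        moved = [a for a in subtree_atoms(bidx) if a != branch.child]
        branch.moved = np.asarray(moved, dtype=int)

    return LigandTopology(
        coords=np.asarray(coords, float),
        names=names,
        atom_types=types,
        charges=np.asarray(charges, float),
        serials=np.asarray(serials, int),
        resnames=resnames,
        root=np.asarray(root_atoms, int),
        branches=branches,
        torsdof=torsdof,
    )


def _format_atom(topology: LigandTopology, idx: int, coord) -> str:
    name = topology.names[idx]
    # PDB convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {int(topology.serials[idx]):5d} {name_field}"
        f" {topology.resnames[idx]:<3s} A   1    "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}    "
        f"{topology.charges[idx]:6.3f} {topology.atom_types[idx]:<2s}"
    )


def _serialize_block(topology: LigandTopology, coords, out: list) -> None:
    out.append("ROOT")
    for idx in topology.root:
        out.append(_format_atom(topology, idx, coords[idx]))
    out.append("ENDROOT")

    def emit_branch(bidx: int) -> None:
        b = topology.branches[bidx]
        sp = int(topology.serials[b.parent])
        sc = int(topology.serials[b.child])
        out.append(f"BRANCH {sp:4d} {sc:4d}")
        for idx in b.block_atoms:
            out.append(_format_atom(topology, idx, coords[idx]))
        for c in b.children:
            emit_branch(c)
        out.append(f"ENDBRANCH {sp:4d} {sc:4d}")

    top_level = set(range(len(topology.branches)))
    for b in topology.branches:
        top_level -= set(b.children)
    for bidx in sorted(top_level):
        emit_branch(bidx)
    out.append(f"TORSDOF {topology.torsdof if topology.torsdof is not None else topology.n_torsions}")


def write_pdbqt_ligand(topology: LigandTopology, path) -> None:
    """Write the topology's reference geometry as a single-block PDBQT ligand."""
    out: list[str] = []
    _serialize_block(topology, topology.coords, out)
    Path(path).write_text("\n".join(out) + "\n")


def write_pdbqt_models(
    topology: LigandTopology,
    poses: Sequence[PoseVector],
    energies: Sequence[float],
    path,
) -> None:
    """Write docked poses as PDBQT MODEL blocks with the energy as a REMARK."""
    if len(poses) != len(energies):
        raise ValueError("poses and energies must have equal length")
    out: list[str] = []
    for i, (pose, energy) in enumerate(zip(poses, energies), start=1):
        coords = apply_pose(topology, pose)
        out.append(f"MODEL {i}")
        out.append(f"REMARK ENERGY {energy:10.3f} kcal/mol")
        _serialize_block(topology, coords, out)
        out.append("ENDMDL")
    Path(path).write_text("\n".join(out) + "\n")
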