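"""Synthetic-data generators: toy ligands and receptor probe complexes.

These fixtures stand in for curated experimental complexes so every search
and diagnostic is testable with no external dataset.  Chemistry is schematic
(carbon chains with idealized bond lengths), but the torsion-tree topology,
PDBQT serialization and the existence of a known global-minimum pose are
faithful to the real docking setup.

A toy complex is built by drawing a random "native" pose inside the docking
box (with a margin so clamping never masks recovery failures), placing probe
points offset from the native atom positions, and assigning each interacting
(atom, probe) pair a 12-6 well whose minimum distance r0 equals that pair's
native separation.  Every pair then sits exactly at its own minimum in the
native pose, which makes the native pose the scorer's global minimum by
construction and its energy exactly -(number of interacting pairs) * depth.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .posemodel import (
    Branch,
    DockingBox,
    LigandTopology,
    PoseVector,
    apply_pose,
    random_unit_quaternion,
    wrap_angle,
)
from .scoring import ToyComplex

__all__ = ["FixtureSpec", "make_toy_ligand", "make_toy_complex"]


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic complex.

    Defaults mirror the benchmark setup at desk scale: a 22.5 A cubic docking
    box, a 6-atom ligand with 2 rotatable bonds, probes offset 5 A from the
    native atoms, an 8 A interaction cutoff and unit well depths.  The probe
    offset sets the well widths (r0 >= 5 A), keeping the native basin wide
    enough that gradient refinement from a 0.5 A perturbation falls back into
    it rather than over the 12-6 wall into an adjacent arrangement.
    """

    n_atoms: int = 6
    n_torsions: int = 2
    box_center: tuple = (0.0, 0.0, 0.0)
    box_extents: tuple = (22.5, 22.5, 22.5)
    probe_offset: float = 5.0   # A, probe distance from its native atom
    cutoff: float = 8.0         # A
    well_depth: float = 1.0     # kcal/mol per interacting pair
    margin: float = 0.2         # native pose kept this fraction away from box faces
    seed: int = 0

    @property
    def box(self) -> DockingBox:
        return DockingBox(np.asarray(self.box_center), np.asarray(self.box_extents))


def make_toy_ligand(n_atoms: int, n_torsions: int, seed: int = 0) -> LigandTopology:
    """Chain-topology ligand with ``n_torsions`` rotatable bonds.

    Atoms form a zig-zag carbon chain (1.5 A bonds, alternating displacement
    plus a small seeded out-of-plane jitter so torsion rotations genuinely
    move atoms).  The chain is split into n_torsions+1 segments: the first is
    the ROOT block, each later segment a nested BRANCH.  The same seed gives
    a byte-identical PDBQT serialization.
    """
    if n_torsions < 0:
        raise ValueError("n_torsions must be >= 0")
    if n_atoms < n_torsions + 2:
        raise ValueError(
            f"need at least {n_torsions + 2} atoms for {n_torsions} rotatable bonds"
        )
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        step = np.array([1.25, 0.85 if i % 2 else -0.85, 0.0])
        step = step / np.linalg.norm(step) * 1.5
        coords[i] = coords[i - 1] + step
    coords += rng.normal(scale=0.05, size=coords.shape)
    charges = np.round(rng.uniform(-0.2, 0.2, size=n_atoms), 3)

    # segment boundaries: root first, then one segment per rotatable bond
    sizes = np.full(n_torsions + 1, n_atoms // (n_torsions + 1))
    sizes[: n_atoms % (n_torsions + 1)] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    root = np.arange(bounds[0], bounds[1])
    branches: list[Branch] = []
    for b in range(n_torsions):
        start, end = bounds[b + 1], bounds[b + 2]
        parent = start - 1
        child = start
        block = list(range(start, end))
        branch = Branch(parent=parent, child=child, moved=np.empty(0, int), block_atoms=block)
        if branches:
            branches[-1].children.append(b)
        branches.append(branch)
    # moved set of branch b = all atoms from its child onward, child excluded
    for b, branch in enumerate(branches):
        branch.moved = np.arange(branch.child + 1, n_atoms)

    return LigandTopology(
        coords=coords,
        names=[f"C{i + 1}" for i in range(n_atoms)],
        atom_types=["C"] * n_atoms,
        charges=charges,
        serials=np.arange(1, n_atoms + 1),
        resnames=["LIG"] * n_atoms,
        root=root,
        branches=branches,
    )


def make_toy_complex(spec: FixtureSpec) -> ToyComplex:
    """Build a synthetic complex whose scorer has a known global-minimum pose."""
    rng = np.random.default_rng(spec.seed)
    topology = make_toy_ligand(spec.n_atoms, spec.n_torsions, seed=spec.seed)
    box = spec.box

    # native pose: away from the box boundary by the configured margin
    inner = box.extents * (1.0 - 2.0 * spec.margin)
    position = box.center + rng.uniform(-inner / 2.0, inner / 2.0)
    native = PoseVector(
        position,
        random_unit_quaternion(rng),
        wrap_angle(rng.uniform(-np.pi, np.pi, size=spec.n_torsions))
        if spec.n_torsions
        else np.zeros(0),
    )
    native_coords = apply_pose(topology, native)

    # one probe per atom, offset in a random direction
    directions = rng.normal(size=(spec.n_atoms, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    probes = native_coords + directions * spec.probe_offset

    r_native = cdist(native_coords, probes)
    # pairs closer than 1 A at the native pose are dropped (a 12-6 well with
    # r0 inside the soft core would break the exact-minimum construction)
    active = (r_native <= spec.cutoff) & (r_native >= 1.0)
    depths = np.where(active, spec.well_depth, 0.0)
    r0 = np.where(depths > 0, r_native, 1.0)  # inert placeholder where depth=0
    native_energy = -float(depths.sum())

    return ToyComplex(
        topology=topology,
        probe_coords=probes,
        depths=depths,
        r0=r0,
        cutoff=spec.cutoff,
        native_pose=native,
        native_energy=native_energy,
    )
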