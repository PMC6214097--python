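"""Baseline conformational searches: Vina-style Monte Carlo and PSO.

Both baselines operate on the same 7+tau pose space, scorer contract and
shared evaluation budget as the CS-DE search, enabling like-for-like
comparisons of search behavior (distance sum, convergence fraction, success
rate) at the same number of maximum energy evaluations.

* :func:`run_mc` reconstructs the Markov-chain Monte Carlo global search that
  the hybrid replaces: a single chain of random-walk mutations, each candidate
  BFGS-refined and then accepted or reverted by the Metropolis criterion.
* :func:`run_pso` is canonical global-best particle swarm optimization with
  the published weights (N=8, omega=0.36, alpha=beta=0.99), with the
  quaternion handled on a 3-component rotation-vector chart so velocities live
  in a vector space, and each evaluated position BFGS-refined before the
  personal/global bests are updated.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.transform import Rotation

from .diagnostics import SearchTrace, distance_sum
from .posemodel import DockingBox, PoseVector, wrap_angle
from .scoring import BudgetedScorer, BudgetExhausted
from .search_core import (
    Nest,
    local_refine,
    random_pose,
    random_walk_offspring,
)

__all__ = ["MCConfig", "PSOConfig", "metropolis_accept", "run_mc", "run_pso"]


@dataclasses.dataclass
class MCConfig:
    """Metropolis Monte Carlo configuration.

    The acceptance scale (kcal/mol) plays the role of kT; 1.2 kcal/mol is the
    package default (config-exposed, not a published constant).  Step sizes
    match the CS-DE random walk.
    """

    scale: float = 1.2              # kcal/mol
    step_position: float = 2.0      # A
    step_orientation: float = 0.25  # rad
    step_torsion: float = 0.5       # rad
    refine: bool = True
    refine_maxiter: int = 100

    def validate(self) -> None:
        if self.scale <= 0:
            raise ValueError("acceptance scale must be positive")


@dataclasses.dataclass
class PSOConfig:
    """Global-best PSO configuration with the published default weights."""

    n_particles: int = 8
    inertia: float = 0.36    # omega
    cognitive: float = 0.99  # alpha
    social: float = 0.99     # beta
    refine: bool = True
    refine_maxiter: int = 100

    def validate(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")


def metropolis_accept(delta_e: float, scale: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept if dE <= 0, else with probability exp(-dE/scale)."""
    if delta_e <= 0:
        return True
    x = delta_e / scale
    if x > 700.0:  # exp underflow guard
        return False
    return rng.random() < math.exp(-x)


def _mc_refine(pose, config, scorer, space):
    if config.refine:
        return local_refine(pose, scorer, space, maxiter=config.refine_maxiter)
    return pose, scorer.evaluate(pose)


def run_mc(
    config: MCConfig,
    space: DockingBox,
    n_torsions: int,
    scorer,
    budget: int,
    seed: int,
):
    """Single-chain Metropolis MC search.

    Iterates {random-walk mutation; BFGS refine; Metropolis accept-or-revert},
    archiving every accepted refined pose.  Returns (ranked nests, trace);
    the trace's DS columns are NaN (a single chain has no agent spread).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    budgeted = BudgetedScorer(scorer, budget)
    trace = SearchTrace()

    current_pose = random_pose(space, n_torsions, rng)
    archive: list[Nest] = []
    try:
        current_pose, current_e = _mc_refine(current_pose, config, budgeted, space)
        archive.append(Nest(current_pose, current_e))
        while budgeted.remaining > 0:
            cand = random_walk_offspring(
                Nest(current_pose, current_e), config, space, rng
            )
            cand, cand_e = _mc_refine(cand, config, budgeted, space)
            if metropolis_accept(cand_e - current_e, config.scale, rng):
                current_pose, current_e = cand, cand_e
                archive.append(Nest(current_pose, current_e))
            trace.record_iteration(
                budgeted.n_evaluations, np.nan, np.nan, 0, 0
            )
    except BudgetExhausted:
        pass

    trace.best_energy = np.asarray(budgeted.best_series)
    trace.n_evaluations = budgeted.n_evaluations
    archive.sort(key=lambda n: n.energy)
    return archive, trace


def _pose_to_chart(pose: PoseVector) -> np.ndarray:
    rotvec = pose.rotation().as_rotvec()
    return np.concatenate([pose.position, rotvec, pose.torsions])


def _chart_to_pose(x: np.ndarray, n_torsions: int) -> PoseVector:
    quat = Rotation.from_rotvec(x[3:6]).as_quat(scalar_first=True)
    return PoseVector(x[:3], quat, wrap_angle(x[6:]) if n_torsions else np.zeros(0))


def _wrap_chart(x: np.ndarray, space: DockingBox, n_torsions: int) -> np.ndarray:
    x = x.copy()
    x[:3] = space.clamp(x[:3])
    if np.linalg.norm(x[3:6]) > np.pi:
        # re-project through the quaternion to the canonical rotation vector
        x[3:6] = Rotation.from_rotvec(x[3:6]).as_rotvec()
    if n_torsions:
        x[6:] = wrap_angle(x[6:])
    return x


def run_pso(
    config: PSOConfig,
    space: DockingBox,
    n_torsions: int,
    scorer,
    budget: int,
    seed: int,
    initial_poses=None,
):
    """Global-best PSO over the pose space.

    v <- omega*v + alpha*r1*(pbest - x) + beta*r2*(gbest - x), per-dimension
    uniform r1, r2; velocities clamped at half the per-block range; positions
    clamped/wrapped per block.  Each particle's position is refined and
    scored, updating its personal best and the swarm's global best; particle
    positions themselves move only by velocity.  Returns (ranked nests,
    trace) with per-iteration DS over the particle positions.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    budgeted = BudgetedScorer(scorer, budget)
    trace = SearchTrace()
    dim = 6 + n_torsions

    if initial_poses is not None:
        if len(initial_poses) != config.n_particles:
            raise ValueError("initial_poses must match n_particles")
        poses = [p.normalized() for p in initial_poses]
    else:
        poses = [random_pose(space, n_torsions, rng) for _ in range(config.n_particles)]
    x = np.stack([_pose_to_chart(p) for p in poses])
    v = np.zeros_like(x)
    v_max = np.concatenate(
        [space.extents / 2.0, np.full(3, np.pi), np.full(n_torsions, np.pi)]
    )

    pbest_x = x.copy()
    pbest_e = np.full(config.n_particles, np.inf)
    archive: list[Nest] = []
    gbest_idx = 0

    def evaluate_particle(i: int) -> None:
        pose = _chart_to_pose(x[i], n_torsions)
        if config.refine:
            pose, e = local_refine(pose, budgeted, space, maxiter=config.refine_maxiter)
        else:
            e = budgeted.evaluate(pose)
        archive.append(Nest(pose, e))
        if e < pbest_e[i]:
            pbest_e[i] = e
            pbest_x[i] = _pose_to_chart(pose)

    try:
        for i in range(config.n_particles):
            evaluate_particle(i)
        gbest_idx = int(np.argmin(pbest_e))
        while budgeted.remaining > 0:
            gbest = pbest_x[gbest_idx]
            for i in range(config.n_particles):
                r1 = rng.random(dim)
                r2 = rng.random(dim)
                v[i] = (
                    config.inertia * v[i]
                    + config.cognitive * r1 * (pbest_x[i] - x[i])
                    + config.social * r2 * (gbest - x[i])
                )
                v[i] = np.clip(v[i], -v_max, v_max)
                x[i] = _wrap_chart(x[i] + v[i], space, n_torsions)
                evaluate_particle(i)
            gbest_idx = int(np.argmin(pbest_e))
            particle_poses = [_chart_to_pose(x[i], n_torsions) for i in range(len(x))]
            trace.record_iteration(
                budgeted.n_evaluations,
                distance_sum(particle_poses),
                np.nan,
                0,
                0,
            )
    except BudgetExhausted:
        pass

    trace.best_energy = np.asarray(budgeted.best_series)
    trace.n_evaluations = budgeted.n_evaluations
    archive.sort(key=lambda n: n.energy)
    return archive, trace
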