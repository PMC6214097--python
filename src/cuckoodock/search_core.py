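"""Hybrid cuckoo-search / differential-evolution (CS-DE) conformational search.

The population of k "nests" (candidate poses) is rank-partitioned into a
*better set* (top ceil(k*(1-P_worse)) by energy) and a *worse set* (the
remaining floor(k*P_worse)).  Each iteration performs two replace operations:

1. cuckoo step — a uniformly chosen nest produces an offspring by a bounded
   random walk (mutating the position, the orientation, or one torsion), the
   offspring is BFGS-refined, and a random *better-set* nest is replaced iff
   the offspring's energy is strictly lower;
2. worse-set rebuild — every worse-set nest is rebuilt through a modified
   differential evolution move: a donor vector x_d = x_r - x_s from two random
   nests, heavy-tailed scale s = u1/u2 (capped), per-block differential
   weights alpha = s * max(block range)/100, and per-element mutation with
   probability P_mutate.

The better set therefore exploits promising regions locally while the worse
set keeps making large, heavy-tailed jumps — the mechanism that maintains
search-space coverage and escapes premature convergence.

All candidate evaluations (including those spent inside BFGS refinement and
its finite-difference gradients) are debited from one shared evaluation
budget, so different algorithms are compared at the same number of maximum
energy evaluations.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize

from .diagnostics import SearchTrace, distance_sum
from .posemodel import DockingBox, PoseVector, random_unit_quaternion, wrap_angle
from .scoring import BudgetedScorer, BudgetExhausted

__all__ = [
    "Nest",
    "Population",
    "SearchConfig",
    "random_pose",
    "initialize_population",
    "random_walk_offspring",
    "cuckoo_step",
    "de_mutate_worse",
    "replace_worse_set",
    "local_refine",
    "run_search",
    "pool_runs",
]

BETTER = "better"
WORSE = "worse"


@dataclasses.dataclass
class Nest:
    """A candidate solution: pose, its scored energy, and set membership."""

    pose: PoseVector
    energy: float
    set_label: str = BETTER


class Population:
    """k ranked nests partitioned into the better and worse sets.

    Nests are kept sorted ascending by energy (stable sort, so ties keep the
    earlier nest first); the last ``n_worse`` are the worse set.
    """

    def __init__(self, nests: list[Nest], n_worse: int) -> None:
        if not 1 <= n_worse <= len(nests) - 1:
            raise ValueError(
                f"worse-set size {n_worse} must leave both sets nonempty "
                f"(k={len(nests)})"
            )
        self.nests = list(nests)
        self.n_worse = n_worse
        self.rank_and_partition()

    def __len__(self) -> int:
        return len(self.nests)

    def rank_and_partition(self) -> None:
        self.nests.sort(key=lambda n: n.energy)  # stable
        for i, nest in enumerate(self.nests):
            nest.set_label = WORSE if i >= len(self.nests) - self.n_worse else BETTER

    @property
    def better(self) -> list[Nest]:
        return [n for n in self.nests if n.set_label == BETTER]

    @property
    def worse(self) -> list[Nest]:
        return [n for n in self.nests if n.set_label == WORSE]

    @property
    def better_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.nests) if n.set_label == BETTER]

    @property
    def worse_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.nests) if n.set_label == WORSE]

    @property
    def worst_better_energy(self) -> float:
        return max(n.energy for n in self.better)

    @property
    def best(self) -> Nest:
        return min(self.nests, key=lambda n: n.energy)

    def poses(self) -> list[PoseVector]:
        return [n.pose for n in self.nests]


@dataclasses.dataclass
class SearchConfig:
    """CS-DE run configuration.

    Defaults follow the published parameterization: k=8 nests, P_worse=0.25
    (so 6 better / 2 worse), P_mutate=0.25.  Random-walk step sizes (2 A
    position sphere, 0.25 rad orientation sigma, 0.5 rad torsion sigma) are
    small relative to each block's range and exposed here; ``s_cap`` bounds
    the heavy-tailed DE scale s = u1/u2.
    """

    k: int = 8
    p_worse: float = 0.25
    p_mutate: float = 0.25
    max_evaluations: int = 10_000
    seed: int = 0
    step_position: float = 2.0      # A, radius of the uniform displacement sphere
    step_orientation: float = 0.25  # rad, sigma of the rotation angle
    step_torsion: float = 0.5       # rad, sigma of the torsion perturbation
    s_cap: float = 100.0
    refine: bool = True             # BFGS-refine cuckoo offspring before comparison
    refine_de: bool = False         # raw-score DE rebuilds (keeps worse-set coverage)
    refine_maxiter: int = 100

    @property
    def n_worse(self) -> int:
        return int(np.floor(self.k * self.p_worse))

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.p_worse < 1.0:
            raise ValueError("P_worse must lie in (0, 1)")
        if not 0.0 <= self.p_mutate <= 1.0:
            raise ValueError("P_mutate must lie in [0, 1]")
        if not 1 <= self.n_worse <= self.k - 1:
            raise ValueError(
                f"floor(k * P_worse) = {self.n_worse} leaves an empty set "
                f"(k={self.k}, P_worse={self.p_worse})"
            )
        if self.max_evaluations < self.k:
            raise ValueError("budget must cover at least the initial population")
        if self.s_cap <= 0:
            raise ValueError("s_cap must be positive")


def random_pose(space: DockingBox, n_torsions: int, rng: np.random.Generator) -> PoseVector:
    """Uniform pose: position in the box, orientation uniform on S^3, torsions
    uniform in (-pi, pi]."""
    return PoseVector(
        space.random_position(rng),
        random_unit_quaternion(rng),
        wrap_angle(rng.uniform(-np.pi, np.pi, size=n_torsions))
        if n_torsions
        else np.zeros(0),
    )


def initialize_population(
    config: SearchConfig,
    space: DockingBox,
    n_torsions: int,
    scorer,
    rng: np.random.Generator,
) -> Population:
    """Sample, score, rank and partition the initial population of k nests."""
    config.validate()
    nests = []
    for _ in range(config.k):
        pose = random_pose(space, n_torsions, rng)
        nests.append(Nest(pose, scorer.evaluate(pose)))
    return Population(nests, config.n_worse)


def random_walk_offspring(
    nest: Nest, config, space: DockingBox, rng: np.random.Generator
) -> PoseVector:
    """Bounded random-walk offspring mutating exactly one pose component.

    The mutation class is chosen uniformly among {position, orientation, one
    torsion} (orientation/position only for rigid ligands): the position is
    displaced by a vector uniform in a sphere of the configured radius and
    clamped to the box; the orientation is composed with a rotation about a
    uniform axis by a Gaussian angle; or one uniformly chosen torsion gets a
    Gaussian perturbation and is re-wrapped.
    """
    pose = nest.pose.copy()
    n_classes = 3 if pose.n_torsions else 2
    choice = int(rng.integers(n_classes))
    if choice == 0:  # position
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            direction = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        radius = config.step_position * rng.random() ** (1.0 / 3.0)
        pose.position = space.clamp(pose.position + direction / norm * radius)
    elif choice == 1:  # orientation
        axis = rng.normal(size=3)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            axis = np.array([0.0, 0.0, 1.0])
            norm = 1.0
        angle = rng.normal(0.0, config.step_orientation) if config.step_orientation > 0 else 0.0
        if angle != 0.0:  # zero-size step is a bit-exact no-op
            from scipy.spatial.transform import Rotation

            delta = Rotation.from_rotvec(axis / norm * angle)
            pose.orientation = (delta * nest.pose.rotation()).as_quat(
                scalar_first=True
            )
    else:  # one torsion
        idx = int(rng.integers(pose.n_torsions))
        step = rng.normal(0.0, config.step_torsion) if config.step_torsion > 0 else 0.0
        if step != 0.0:
            pose.torsions[idx] = wrap_angle(pose.torsions[idx] + step)
    return pose


def local_refine(
    pose: PoseVector,
    scorer,
    space: DockingBox | None = None,
    maxiter: int = 100,
):
    """Quasi-Newton (BFGS) refinement of a pose in the 7+tau parameterization.

    The objective canonicalizes each trial point (unit quaternion, wrapped
    torsions) before scoring; analytic gradients are chain-ruled through the
    normalization when the scorer provides them, otherwise scipy's
    finite-difference gradient is used and every probe counts as one
    evaluation.  Returns the best in-box pose seen, so the returned energy
    never exceeds the input pose's energy.  Raises :class:`BudgetExhausted`
    only if not even the starting pose could be evaluated.
    """
    tau = pose.n_torsions
    best = {"pose": None, "energy": np.inf}

    def canonical(x: np.ndarray) -> PoseVector:
        return PoseVector.from_array(x, tau).normalized()

    def track(p: PoseVector, e: float) -> None:
        if e < best["energy"] and (space is None or space.contains(p.position)):
            best["pose"] = p
            best["energy"] = e

    if scorer.has_gradient:

        def fun(x):
            p = canonical(x)
            e, g_canon = scorer.evaluate_with_gradient(p)
            track(p, e)
            # chain rule for quaternion normalization; wrap is identity
            q = x[3:7]
            n = np.linalg.norm(q)
            u = q / n
            g = np.array(g_canon, dtype=float)
            g[3:7] = (g_canon[3:7] - u * float(np.dot(u, g_canon[3:7]))) / n
            return e, g

        jac = True
    else:

        def fun(x):
            p = canonical(x)
            e = scorer.evaluate(p)
            track(p, e)
            return e

        jac = None

    x0 = pose.normalized().as_array()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # line-search / precision chatter
            minimize(fun, x0, jac=jac, method="BFGS", options={"maxiter": maxiter})
    except BudgetExhausted:
        if best["pose"] is None:
            raise
    if best["pose"] is None or not np.isfinite(best["energy"]):
        # non-finite start: return the pose unrefined with a warning record
        warnings.warn("non-finite energy at refinement start; pose returned unrefined")
        e0 = best["energy"] if best["pose"] is not None else np.nan
        return pose.normalized(), e0
    return best["pose"], best["energy"]


def _score_candidate(pose: PoseVector, config, scorer, space: DockingBox, refine: bool):
    """Refine-and-score (or raw-score) one candidate."""
    if refine:
        return local_refine(pose, scorer, space, maxiter=config.refine_maxiter)
    return pose, scorer.evaluate(pose)


def cuckoo_step(
    pop: Population,
    config: SearchConfig,
    scorer,
    space: DockingBox,
    rng: np.random.Generator,
):
    """One first-replace operation.

    A uniformly random nest (the cuckoo parent, drawn from the whole
    population) produces a random-walk offspring, which is refined and scored;
    a uniformly random *better-set* nest x_j is replaced iff the offspring's
    energy is strictly lower.  Returns (population, replaced, important) where
    ``important`` flags an offspring beating the worst better-set nest.

    On budget exhaustion the step aborts cleanly: partial evaluations are
    counted and the exception propagates with the population unchanged.
    """
    parent = pop.nests[int(rng.integers(len(pop)))]
    offspring = random_walk_offspring(parent, config, space, rng)
    offspring, energy = _score_candidate(offspring, config, scorer, space, config.refine)
    important = energy < pop.worst_better_energy
    better_idx = pop.better_indices
    j = better_idx[int(rng.integers(len(better_idx)))]
    replaced = False
    # a no-op mutation lays no egg: a bit-identical clone of its parent never
    # replaces another nest (only reachable with zero step sizes)
    is_clone = np.array_equal(offspring.as_array(), parent.pose.as_array())
    if not is_clone and energy < pop.nests[j].energy:
        pop.nests[j] = Nest(offspring, energy)
        pop.rank_and_partition()
        replaced = True
    return pop, replaced, important


def de_mutate_worse(
    x_w: Nest,
    pop: Population,
    config: SearchConfig,
    space: DockingBox,
    rng: np.random.Generator,
) -> PoseVector:
    """Modified-DE mutation of one worse-set nest.

    Donor x_d = x_r - x_s from two distinct random nests (quaternions
    subtracted component-wise, torsions as wrapped angular differences);
    heavy-tailed scale s = u1/u2 capped at ``s_cap``; per-block weights
    alpha_p = s*max(box extent)/100, alpha_o = alpha_t = s*pi/100; each of the
    7+tau elements updated independently with probability P_mutate.  The
    result is clamped/renormalized/wrapped per block.
    """
    if len(pop) < 3:
        raise ValueError("DE mutation needs a population of at least 3 nests")
    k = len(pop)
    i_r = int(rng.integers(k))
    i_s = int(rng.integers(k))
    while i_s == i_r:
        i_s = int(rng.integers(k))
    x_r = pop.nests[i_r].pose
    x_s = pop.nests[i_s].pose

    donor = np.concatenate(
        [
            x_r.position - x_s.position,
            x_r.orientation - x_s.orientation,
            wrap_angle(x_r.torsions - x_s.torsions)
            if x_r.n_torsions
            else np.zeros(0),
        ]
    )

    u1 = float(rng.random())
    u2 = float(rng.random())
    while u2 == 0.0:
        u2 = float(rng.random())
    s = min(u1 / u2, config.s_cap)
    alpha_p = s * float(np.max(space.extents)) / 100.0
    alpha_o = s * np.pi / 100.0
    alpha_t = s * np.pi / 100.0
    tau = x_w.pose.n_torsions
    alpha = np.concatenate(
        [np.full(3, alpha_p), np.full(4, alpha_o), np.full(tau, alpha_t)]
    )

    x = x_w.pose.normalized().as_array()
    mask = rng.random(7 + tau) < config.p_mutate
    x = np.where(mask, x + alpha * donor, x)

    position = space.clamp(x[:3])
    quat = x[3:7]
    norm = np.linalg.norm(quat)
    if norm < 1e-12:
        quat = random_unit_quaternion(rng)
    else:
        quat = quat / norm
    torsions = wrap_angle(x[7:]) if tau else np.zeros(0)
    return PoseVector(position, quat, torsions)


def replace_worse_set(
    pop: Population,
    config: SearchConfig,
    scorer,
    space: DockingBox,
    rng: np.random.Generator,
):
    """Second-replace operation: rebuild every worse-set nest via modified DE.

    Each rebuilt solution is refined and scored; an *important update* is
    counted when a rebuilt solution's energy beats the worst better-set nest
    (measured against the pre-step better-set maximum).  The population is
    re-ranked and re-partitioned afterwards.  On budget exhaustion the
    replacement is partial but the population is still consistently re-ranked
    before the exception propagates.
    """
    pre_worst_better = pop.worst_better_energy
    n_important = 0
    try:
        for idx in pop.worse_indices:
            new_pose = de_mutate_worse(pop.nests[idx], pop, config, space, rng)
            new_pose, energy = _score_candidate(
                new_pose, config, scorer, space, config.refine_de
            )
            if energy < pre_worst_better:
                n_important += 1
            pop.nests[idx] = Nest(new_pose, energy, WORSE)
    except BudgetExhausted:
        pop.rank_and_partition()
        raise
    pop.rank_and_partition()
    return pop, n_important


def run_search(
    config: SearchConfig,
    space: DockingBox,
    n_torsions: int,
    scorer,
):
    """Full CS-DE run: iterate {cuckoo step; worse-set rebuild} until the
    evaluation budget is exhausted.

    Returns (ranked nests, :class:`SearchTrace`).  The trace records the
    best-so-far energy after every evaluation and, per iteration, the
    all-agent DS, the better-set DS and the cumulative important-update
    counters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    budgeted = BudgetedScorer(scorer, config.max_evaluations)
    trace = SearchTrace()
    cum_better = 0
    cum_worse = 0

    def record(pop: Population) -> None:
        ds_all = distance_sum(pop.poses())
        better_poses = [n.pose for n in pop.better]
        ds_b = distance_sum(better_poses) if len(better_poses) >= 2 else np.nan
        trace.record_iteration(
            budgeted.n_evaluations, ds_all, ds_b, cum_better, cum_worse
        )

    pop = initialize_population(config, space, n_torsions, budgeted, rng)
    try:
        while budgeted.remaining > 0:
            pop, _, important = cuckoo_step(pop, config, budgeted, space, rng)
            cum_better += int(important)
            pop, n_imp = replace_worse_set(pop, config, budgeted, space, rng)
            cum_worse += n_imp
            record(pop)
    except BudgetExhausted:
        pop.rank_and_partition()
        record(pop)

    trace.best_energy = np.asarray(budgeted.best_series)
    trace.n_evaluations = budgeted.n_evaluations
    pop.rank_and_partition()
    return list(pop.nests), trace


def pool_runs(run_results, top_n: int):
    """Pool ranked solutions from independent runs and keep the top ``top_n``.

    Emulates multi-threaded docking: each thread is an independent seeded run
    and the union of their solutions is re-ranked by energy.
    """
    solutions = [nest for run in run_results for nest in run]
    if not solutions:
        raise ValueError("no runs to pool")
    solutions.sort(key=lambda n: n.energy)
    return solutions[:top_n]
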