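"""CS-DE search tests: partitioning, mutation operators, refinement, full runs."""
import numpy as np
import pytest

from cuckoodock import (
    BudgetedScorer,
    DockingBox,
    Nest,
    PoseVector,
    Population,
    SearchConfig,
    cuckoo_step,
    de_mutate_worse,
    initialize_population,
    local_refine,
    multifunnel_landscape,
    pool_runs,
    quadratic_landscape,
    random_pose,
    random_walk_offspring,
    replace_worse_set,
    run_search,
    wrap_angle,
)


def center_pose(box, tau=2):
    return PoseVector(box.center, [1.0, 0.0, 0.0, 0.0], np.zeros(tau))


def quad_scorer(box, tau=2):
    return quadratic_landscape(center_pose(box, tau), np.ones(7 + tau))


class StubRNG:
    """Deterministic stand-in for a Generator, driving de_mutate_worse."""

    def __init__(self, ints, floats, mask_values):
        self.ints = list(ints)
        self.floats = list(floats)
        self.mask_values = mask_values

    def integers(self, k):
        return self.ints.pop(0)

    def random(self, size=None):
        if size is None:
            return self.floats.pop(0)
        return np.asarray(self.mask_values[:size], dtype=float)


class TestPopulation:
    def test_default_partition_is_six_better_two_worse(self, box, rng):
        config = SearchConfig()
        pop = initialize_population(config, box, 2, quad_scorer(box), rng)
        assert len(pop.better) == 6
        assert len(pop.worse) == 2

    def test_small_population_forces_single_worse_nest(self, box, rng):
        config = SearchConfig(k=4)
        pop = initialize_population(config, box, 2, quad_scorer(box), rng)
        assert len(pop.worse) == 1

    def test_best_nest_always_in_better_set(self, box):
        for seed in range(5):
            gen = np.random.default_rng(seed)
            pop = initialize_population(
                SearchConfig(), box, 2, quad_scorer(box), gen
            )
            assert pop.best.set_label == "better"

    def test_partition_energy_ordering_invariant(self, box, rng):
        pop = initialize_population(SearchConfig(), box, 2, quad_scorer(box), rng)
        assert max(n.energy for n in pop.better) <= min(n.energy for n in pop.worse)

    @pytest.mark.parametrize(
        "kwargs", [{"k": 1}, {"k": 8, "p_worse": 0.05}, {"p_worse": 0.0}, {"p_worse": 1.0}]
    )
    def test_degenerate_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchConfig(**kwargs).validate()

    def test_initial_poses_sampled_inside_domain(self, box, rng):
        pop = initialize_population(SearchConfig(), box, 2, quad_scorer(box), rng)
        for nest in pop.nests:
            assert box.contains(nest.pose.position)
            assert np.linalg.norm(nest.pose.orientation) == pytest.approx(1.0)
            assert np.all(nest.pose.torsions > -np.pi)
            assert np.all(nest.pose.torsions <= np.pi)


class TestRandomWalk:
    def test_mutates_exactly_one_block(self, box, rng):
        config = SearchConfig()
        parent = Nest(random_pose(box, 2, rng), 0.0)
        for _ in range(50):
            child = random_walk_offspring(parent, config, box, rng)
            changed = [
                not np.allclose(child.position, parent.pose.position),
                not np.allclose(child.orientation, parent.pose.orientation),
                not np.allclose(child.torsions, parent.pose.torsions),
            ]
            assert sum(changed) <= 1  # exactly one class perturbed (may be a no-op draw)

    def test_rigid_ligand_never_touches_torsions(self, box, rng):
        config = SearchConfig()
        parent = Nest(random_pose(box, 0, rng), 0.0)
        for _ in range(20):
            child = random_walk_offspring(parent, config, box, rng)
            assert child.torsions.size == 0

    def test_zero_steps_reproduce_parent(self, box, rng):
        config = SearchConfig(step_position=0.0, step_orientation=0.0, step_torsion=0.0)
        parent = Nest(random_pose(box, 2, rng), 0.0)
        for _ in range(10):
            child = random_walk_offspring(parent, config, box, rng)
            assert np.allclose(child.as_array(), parent.pose.as_array(), atol=1e-12)

    def test_offspring_position_always_inside_box(self, rng):
        box = DockingBox([0.0, 0.0, 0.0], [6.0, 6.0, 6.0])
        config = SearchConfig(step_position=5.0)
        parent = Nest(
            PoseVector(box.upper - 0.1, [1, 0, 0, 0], np.zeros(2)), 0.0
        )
        for _ in range(10_000):
            child = random_walk_offspring(parent, config, box, rng)
            assert box.contains(child.position)


class TestDEMutation:
    def _population(self, box, poses_arrays, n_worse=2):
        nests = [
            Nest(PoseVector.from_array(a, (len(a) - 7)), float(i))
            for i, a in enumerate(poses_arrays)
        ]
        return Population(nests, n_worse)

    def test_zero_mutation_probability_is_identity(self, box, rng):
        config = SearchConfig(p_mutate=0.0)
        pop = initialize_population(
            SearchConfig(), box, 2, quad_scorer(box), rng
        )
        target = pop.worse[0]
        out = de_mutate_worse(target, pop, config, box, rng)
        assert np.allclose(out.as_array(), target.pose.normalized().as_array())

    def test_identical_donor_pair_leaves_pose_unchanged(self, box):
        # nests 0 and 1 share a pose, so the donor vector is exactly zero
        shared = np.array([1.0, 2.0, 3.0, 1.0, 0.0, 0.0, 0.0, 0.5, -0.5])
        arrays = [shared, shared.copy()] + [
            np.array([i, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]) for i in (4.0, 5.0)
        ]
        pop = self._population(box, arrays, n_worse=1)
        target = pop.worse[0]
        stub = StubRNG(ints=[0, 1], floats=[0.5, 0.25], mask_values=np.zeros(9))
        out = de_mutate_worse(target, pop, SearchConfig(p_mutate=1.0), box, stub)
        assert np.allclose(out.as_array(), target.pose.normalized().as_array())

    def test_stubbed_rng_matches_elementwise_hand_computation(self, box):
        arrays = [
            np.array([1.0, 2.0, 3.0, 1.0, 0.0, 0.0, 0.0, 0.5, -0.5]),
            np.array([-2.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, -1.0, 1.5]),
            np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
            np.array([4.0, 4.0, 4.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1.0]),
        ]
        pop = self._population(box, arrays, n_worse=1)
        target = pop.worse[0]
        x_w = target.pose.normalized().as_array()
        # stub: x_r = nests[0], x_s = nests[1]; u1=0.5, u2=0.25 -> s=2; mutate all
        stub = StubRNG(ints=[0, 1], floats=[0.5, 0.25], mask_values=np.zeros(9))
        out = de_mutate_worse(target, pop, SearchConfig(p_mutate=1.0), box, stub)

        x_r, x_s = pop.nests[0].pose, pop.nests[1].pose
        donor = np.concatenate(
            [
                x_r.position - x_s.position,
                x_r.orientation - x_s.orientation,
                wrap_angle(x_r.torsions - x_s.torsions),
            ]
        )
        s = 0.5 / 0.25
        alpha = np.concatenate(
            [
                np.full(3, s * 22.5 / 100),
                np.full(4, s * np.pi / 100),
                np.full(2, s * np.pi / 100),
            ]
        )
        expected = x_w + alpha * donor
        expected[:3] = np.clip(expected[:3], box.lower, box.upper)
        expected[3:7] = expected[3:7] / np.linalg.norm(expected[3:7])
        expected[7:] = wrap_angle(expected[7:])
        assert np.allclose(out.as_array(), expected, atol=1e-12)

    def test_heavy_tail_scale_is_capped(self, box):
        arrays = [
            np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
            np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
        ]
        pop = self._population(box, arrays, n_worse=1)
        target = pop.worse[0]
        # u1/u2 = 0.9/1e-9 would be 9e8 without the cap
        stub = StubRNG(ints=[0, 1], floats=[0.9, 1e-9], mask_values=np.zeros(9))
        config = SearchConfig(p_mutate=1.0, s_cap=100.0)
        out = de_mutate_worse(target, pop, config, box, stub)
        # with s capped at 100: alpha_p = 100*22.5/100 = 22.5, donor_x = 1
        assert np.all(out.position <= box.upper + 1e-12)
        assert np.isfinite(out.as_array()).all()


class TestWorseSetReplacement:
    def test_important_update_count_matches_recount_oracle(self, box):
        class Recorder:
            """Counting shim exposing every energy the search charged."""

            def __init__(self, inner):
                self.inner = inner
                self.energies = []
                self.has_gradient = inner.has_gradient

            def evaluate(self, pose):
                e = self.inner.evaluate(pose)
                self.energies.append(e)
                return e

            def evaluate_with_gradient(self, pose):
                e, g = self.inner.evaluate_with_gradient(pose)
                self.energies.append(e)
                return e, g

        for seed in range(10):
            gen = np.random.default_rng(seed)
            config = SearchConfig()  # refine_de False: one eval per rebuild
            scorer = Recorder(multifunnel_landscape(box, 2, seed=seed))
            pop = initialize_population(config, box, 2, scorer, gen)
            pre_worst_better = pop.worst_better_energy
            scorer.energies.clear()
            _, n_important = replace_worse_set(pop, config, scorer, box, gen)
            oracle = sum(e < pre_worst_better for e in scorer.energies)
            assert n_important == oracle

    def test_no_updates_when_rebuilds_are_worse(self, box, rng):
        config = SearchConfig()
        scorer = quad_scorer(box)
        pop = initialize_population(config, box, 2, scorer, rng)
        # make the better set unbeatable
        for nest in pop.better:
            nest.energy = -1e9
        pop.rank_and_partition()
        _, n_important = replace_worse_set(pop, config, scorer, box, rng)
        assert n_important == 0

    def test_winning_rebuild_enters_better_set(self, box, rng):
        config = SearchConfig(refine_de=True)
        scorer = quad_scorer(box)
        budgeted = BudgetedScorer(scorer, 10_000)
        pop = initialize_population(config, box, 2, budgeted, rng)
        # refined rebuilds on a convex bowl reach ~0, beating random better nests
        pop, n_important = replace_worse_set(pop, config, budgeted, box, rng)
        if n_important:
            assert pop.best.energy == pytest.approx(0.0, abs=1e-6)
            assert pop.best.set_label == "better"


class TestLocalRefine:
    def test_converges_on_convex_objective(self, box, rng):
        scorer = quad_scorer(box)
        budgeted = BudgetedScorer(scorer, 2000)
        start = random_pose(box, 2, rng)
        refined, energy = local_refine(start, budgeted, box, maxiter=100)
        assert energy < 1e-6
        assert np.allclose(refined.position, box.center, atol=1e-3)

    def test_pose_at_minimum_returned_unchanged(self, box):
        scorer = quad_scorer(box)
        budgeted = BudgetedScorer(scorer, 2000)
        opt = center_pose(box)
        refined, energy = local_refine(opt, budgeted, box)
        assert energy == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(refined.position, opt.position, atol=1e-9)

    def test_never_increases_energy_across_seeded_starts(self, box):
        scorer = multifunnel_landscape(box, 2, seed=11)
        gen = np.random.default_rng(0)
        budgeted = BudgetedScorer(scorer, 200_000)
        for _ in range(1000):
            start = random_pose(box, 2, gen)
            e_start = budgeted.evaluate(start)
            _, e_ref = local_refine(start, budgeted, box)
            assert e_ref <= e_start + 1e-12


class TestRunSearch:
    def test_best_so_far_non_increasing_and_budget_respected(self, box):
        scorer = multifunnel_landscape(box, 2, seed=2)
        config = SearchConfig(seed=3, max_evaluations=2000)
        _, trace = run_search(config, box, 2, scorer)
        assert np.all(np.diff(trace.best_energy) <= 0)
        assert scorer.n_evaluations <= 2000
        assert trace.n_evaluations == scorer.n_evaluations
        assert np.all(np.diff(trace.eval_index) > 0)

    def test_reaches_quadratic_optimum(self, box):
        config = SearchConfig(seed=1, max_evaluations=5000)
        solutions, _ = run_search(config, box, 2, quad_scorer(box))
        assert solutions[0].energy < 1e-3

    def test_same_seed_identical_traces(self, box):
        results = []
        for _ in range(2):
            scorer = multifunnel_landscape(box, 2, seed=4)
            solutions, trace = run_search(
                SearchConfig(seed=7, max_evaluations=1500), box, 2, scorer
            )
            results.append((solutions, trace))
        (s1, t1), (s2, t2) = results
        assert np.array_equal(t1.best_energy, t2.best_energy)
        assert t1.eval_index == t2.eval_index
        assert t1.ds == t2.ds
        assert np.allclose(
            [n.energy for n in s1], [n.energy for n in s2]
        )

    def test_null_dynamics_leave_population_invariant(self, box):
        config = SearchConfig(
            p_mutate=0.0,
            step_position=0.0,
            step_orientation=0.0,
            step_torsion=0.0,
            refine=False,
            refine_de=False,
            max_evaluations=10_000,
            seed=5,
        )
        gen = np.random.default_rng(config.seed)
        scorer = BudgetedScorer(multifunnel_landscape(box, 2, seed=5), 10_000)
        pop = initialize_population(config, box, 2, scorer, gen)
        before = sorted(tuple(n.pose.normalized().as_array()) for n in pop.nests)
        for _ in range(100):
            pop, _, _ = cuckoo_step(pop, config, scorer, box, gen)
            pop, _ = replace_worse_set(pop, config, scorer, box, gen)
        after = sorted(tuple(n.pose.normalized().as_array()) for n in pop.nests)
        assert np.allclose(np.asarray(before), np.asarray(after), atol=1e-12)

    def test_partition_invariant_holds_each_iteration(self, box):
        config = SearchConfig(seed=9, max_evaluations=1500)
        gen = np.random.default_rng(config.seed)
        scorer = BudgetedScorer(multifunnel_landscape(box, 2, seed=9), 1500)
        pop = initialize_population(config, box, 2, scorer, gen)
        from cuckoodock import BudgetExhausted

        try:
            for _ in range(50):
                pop, _, _ = cuckoo_step(pop, config, scorer, box, gen)
                pop, _ = replace_worse_set(pop, config, scorer, box, gen)
                assert max(n.energy for n in pop.better) <= min(
                    n.energy for n in pop.worse
                )
        except BudgetExhausted:
            pass


class TestPooling:
    def test_single_run_pooling_is_truncation(self, box):
        scorer = multifunnel_landscape(box, 2, seed=1)
        solutions, _ = run_search(
            SearchConfig(seed=1, max_evaluations=1000), box, 2, scorer
        )
        pooled = pool_runs([solutions], top_n=3)
        assert [n.energy for n in pooled] == [n.energy for n in solutions[:3]]

    def test_pooled_best_bounds_every_run(self, box):
        runs = []
        for seed in range(4):
            scorer = multifunnel_landscape(box, 2, seed=6)
            solutions, _ = run_search(
                SearchConfig(seed=seed, max_evaluations=1000), box, 2, scorer
            )
            runs.append(solutions)
        pooled = pool_runs(runs, top_n=8)
        assert all(pooled[0].energy <= r[0].energy for r in runs)

    def test_pooling_raises_global_funnel_hit_rate(self, box):
        landscape_seed = 13
        gm = multifunnel_landscape(box, 2, seed=landscape_seed)
        gm_energy = gm.evaluate(gm.global_minimum_pose)
        hits, runs = [], []
        for seed in range(8):
            scorer = multifunnel_landscape(box, 2, seed=landscape_seed)
            solutions, _ = run_search(
                SearchConfig(seed=seed, max_evaluations=1200), box, 2, scorer
            )
            runs.append(solutions)
            hits.append(solutions[0].energy < gm_energy + 1.0)
        pooled = pool_runs(runs, top_n=1)
        pooled_hit = pooled[0].energy < gm_energy + 1.0
        assert pooled_hit >= max(np.mean(hits), any(hits) * 0.0)
        assert pooled[0].energy <= min(r[0].energy for r in runs)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            pool_runs([], top_n=1)
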