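"""Osprey optimizer: elementary moves, chaos stream, loop invariants."""

import numpy as np
import pytest

from ospreycaps.benchmarks import get_function
from ospreycaps.optimizer import (OptimizerConfig, Population, SearchSpace,
                                  clip_to_bounds, fish_set, gaussian_mutation,
                                  greedy_select, initialize_population,
                                  phase1_update, phase2_update, run,
                                  sinusoidal_chaos_stream)


def sphere(x):
    return float(np.sum(np.square(x)))


def make_pop(Y, A):
    return Population(Y=np.asarray(Y, dtype=float), A=np.asarray(A, dtype=float))


class TestSearchSpace:
    def test_rejects_degenerate_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(np.zeros(3), np.zeros(3))

    def test_cube(self):
        s = SearchSpace.cube(-1, 1, 4)
        assert s.m == 4
        assert np.all(s.lb == -1) and np.all(s.ub == 1)


class TestInitialization:
    def test_positions_within_bounds_and_fitness_consistent(self):
        space = SearchSpace.cube(-1, 1, 6)
        pop = initialize_population(space, 50, np.random.default_rng(0), sphere)
        assert pop.Y.shape == (50, 6)
        assert np.all(pop.Y >= -1) and np.all(pop.Y <= 1)
        assert np.allclose(pop.A, [sphere(y) for y in pop.Y])
        assert pop.best_value == pop.A.min()

    def test_fixed_seed_reproducible(self):
        space = SearchSpace.cube(-5, 5, 3)
        p1 = initialize_population(space, 10, np.random.default_rng(3), sphere)
        p2 = initialize_population(space, 10, np.random.default_rng(3), sphere)
        assert np.array_equal(p1.Y, p2.Y)


class TestFishSet:
    def test_strictly_better_members_plus_best(self):
        pop = make_pop(np.zeros((4, 1)), [5, 2, 9, 1])
        assert set(fish_set(pop, 0)) == {1, 3}

    def test_best_member_sees_only_itself(self):
        pop = make_pop(np.zeros((4, 1)), [5, 2, 9, 1])
        assert set(fish_set(pop, 3)) == {3}

    def test_all_equal_fitness_gives_first_index(self):
        pop = make_pop(np.zeros((4, 1)), [2, 2, 2, 2])
        for i in range(4):
            assert set(fish_set(pop, i)) == {0}

    def test_single_member_population(self):
        pop = make_pop(np.zeros((1, 1)), [3.0])
        assert set(fish_set(pop, 0)) == {0}


class TestPhaseUpdates:
    def test_phase1_hand_examples(self):
        pop = make_pop([[2.0]], [4.0])
        sa = np.array([4.0])
        assert phase1_update(pop, 0, sa, np.array([0.5]), np.array([1])) == 3.0
        assert phase1_update(pop, 0, sa, np.array([0.0]), np.array([1])) == 2.0
        assert phase1_update(pop, 0, sa, np.array([1.0]), np.array([2])) == 2.0

    def test_phase2_hand_example(self):
        space = SearchSpace.cube(-100, 100, 1)
        pop = make_pop([[0.0]], [0.0])
        cand = phase2_update(pop, 0, np.array([0.75]), 10, space)
        assert cand[0] == pytest.approx(5.0)  # (-100 + 0.75*200)/10

    def test_phase2_midpoint_cancels(self):
        space = SearchSpace.cube(-7, 7, 3)
        pop = make_pop([[1.0, 2.0, 3.0]], [0.0])
        cand = phase2_update(pop, 0, np.full(3, 0.5), 4, space)
        assert np.allclose(cand, pop.Y[0])

    def test_phase2_step_shrinks_with_iteration(self):
        space = SearchSpace.cube(-100, 100, 1)
        pop = make_pop([[0.0]], [0.0])
        for t in (1, 10, 1000):
            cand = phase2_update(pop, 0, np.array([1.0]), t, space)
            assert abs(cand[0]) <= 100.0 / t + 1e-12

    def test_phase2_rejects_zero_iteration(self):
        space = SearchSpace.cube(-1, 1, 1)
        with pytest.raises(ValueError):
            phase2_update(make_pop([[0.0]], [0.0]), 0, np.array([0.5]), 0, space)


class TestClipAndGreedy:
    def test_clip_examples(self):
        space = SearchSpace.cube(-100, 100, 1)
        assert clip_to_bounds(np.array([150.0]), space)[0] == 100.0
        assert clip_to_bounds(np.array([-150.0]), space)[0] == -100.0
        assert clip_to_bounds(np.array([42.0]), space)[0] == 42.0

    def test_greedy_is_strict(self):
        pop = make_pop([[0.0]], [5.0])
        assert greedy_select(pop, 0, np.array([1.0]), 3.0)
        assert pop.A[0] == 3.0
        assert not greedy_select(pop, 0, np.array([2.0]), 3.0)  # tie kept
        assert not greedy_select(pop, 0, np.array([2.0]), 7.0)
        assert pop.Y[0, 0] == 1.0


class TestChaosStream:
    def test_first_iterates(self):
        assert sinusoidal_chaos_stream(0.7, 2.3, 1)[0] == pytest.approx(
            2.3 * 0.49 * np.sin(0.7 * np.pi))
        assert sinusoidal_chaos_stream(0.5, 2.3, 1)[0] == pytest.approx(0.575)

    @pytest.mark.parametrize("p0", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_seed_rejected(self, p0):
        with pytest.raises(ValueError):
            sinusoidal_chaos_stream(p0, 2.3, 1)

    def test_stays_in_unit_interval_and_non_degenerate(self):
        s = sinusoidal_chaos_stream(0.7, 2.3, length=100_000)
        assert np.all((s > 0.0) & (s < 1.0))
        tail = s[-1000:]
        assert np.std(tail) > 1e-3  # not eventually constant
        assert len(np.unique(np.round(tail, 12))) > 100

    def test_burn_in_advances_the_stream(self):
        a = sinusoidal_chaos_stream(0.7, 2.3, length=5, burn_in=10)
        b = sinusoidal_chaos_stream(0.7, 2.3, length=15)[10:]
        assert np.allclose(a, b)


class TestGaussianMutation:
    def test_zero_scale_is_identity(self):
        x = np.array([1.0, -2.0, 3.0])
        out = gaussian_mutation(x, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_zero_vector_fixed_for_any_scale(self):
        out = gaussian_mutation(np.zeros(4), 0.9, np.random.default_rng(0))
        assert np.array_equal(out, np.zeros(4))

    def test_seeded_reproducibility(self):
        x = np.ones(5)
        a = gaussian_mutation(x, 0.3, np.random.default_rng(11))
        b = gaussian_mutation(x, 0.3, np.random.default_rng(11))
        assert np.array_equal(a, b)


class TestRunLoop:
    @pytest.mark.parametrize("variant", ["ooa", "mop"])
    def test_history_monotone_and_bounds_respected(self, variant):
        f = get_function("griewank", 3)
        space = SearchSpace.cube(f.lower_bound, f.upper_bound, 3)
        for seed in range(10):
            res = run(f, space, OptimizerConfig(N=5, T=10, variant=variant,
                                                seed=seed))
            assert np.all(np.diff(res.history) <= 0.0)
            assert res.best_value == res.history[-1]
            assert np.all(res.best_position >= space.lb)
            assert np.all(res.best_position <= space.ub)

    def test_bit_identical_for_same_seed(self):
        space = SearchSpace.cube(-10, 10, 4)
        cfg = OptimizerConfig(N=6, T=8, variant="mop", seed=99)
        r1 = run(sphere, space, cfg)
        r2 = run(sphere, space, cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.history, r2.history)
        assert r1.evaluations == r2.evaluations

    def test_minimal_loop(self):
        space = SearchSpace.cube(-1, 1, 2)
        res = run(sphere, space, OptimizerConfig(N=2, T=1, variant="ooa", seed=0))
        assert res.history.shape == (1,)

    def test_evaluation_counts(self):
        space = SearchSpace.cube(-1, 1, 2)
        N, T = 4, 6
        ooa = run(sphere, space, OptimizerConfig(N=N, T=T, variant="ooa", seed=0))
        assert ooa.evaluations == N + 2 * N * T
        mop = run(sphere, space, OptimizerConfig(N=N, T=T, variant="mop", seed=0))
        assert mop.evaluations == N + 3 * N * T  # extra mutation step

    def test_final_best_not_worse_than_initial(self):
        space = SearchSpace.cube(-100, 100, 2)
        res = run(sphere, space, OptimizerConfig(N=10, T=50, variant="ooa", seed=1))
        assert res.best_value <= res.history[0]

    def test_non_finite_objective_raises(self):
        space = SearchSpace.cube(-1, 1, 2)

        def bad(x):
            return float("nan")

        with pytest.raises(ValueError, match="non-finite"):
            run(bad, space, OptimizerConfig(N=2, T=1, seed=0))

    def test_sphere_convergence_floor(self):
        # deep-convergence sanity on a 2-D sphere
        space = SearchSpace.cube(-100, 100, 2)
        finals = [
            run(sphere, space,
                OptimizerConfig(N=30, T=200, variant="mop", seed=s)).best_value
            for s in range(20)
        ]
        assert np.median(finals) < 1e-3

    def test_mop_not_worse_than_ooa_on_sphere_paired_seeds(self):
        # seed-paired comparison of the modified variant against the base
        # algorithm at the reference benchmark scale
        f = get_function("sphere", 10)
        space = SearchSpace.cube(f.lower_bound, f.upper_bound, 10)
        finals = {v: [] for v in ("mop", "ooa")}
        for variant in finals:
            for seed in range(20):
                res = run(f, space, OptimizerConfig(N=30, T=200,
                                                    variant=variant, seed=seed))
                finals[variant].append(res.best_value)
        assert np.mean(finals["mop"]) <= np.mean(finals["ooa"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(N=1)
        with pytest.raises(ValueError):
            OptimizerConfig(T=0)
        with pytest.raises(ValueError):
            OptimizerConfig(variant="pso")
        with pytest.raises(ValueError):
            OptimizerConfig(chaos_a=5.0)
        with pytest.raises(ValueError):
            OptimizerConfig(chaos_p0=1.0)
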