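"""Hybrid seek optimizer: update-rule arithmetic, invariants, convergence."""

import numpy as np
import pytest
from scipy import stats

import hybridseek as hs
from hybridseek.errors import EvaluationError, ParameterError
from hybridseek.optimizer import (
    clamp_feasible,
    corvid_step,
    gregarious_step,
    hybrid_step,
    initialize,
    update_memory,
)


def sphere(x):
    return float(-np.sum(np.asarray(x) ** 2))


def _state(positions, fitness, memories=None, memory_fitness=None, velocity=None,
           bounds=((-10.0, 10.0),), seed=0):
    positions = np.atleast_2d(np.asarray(positions, float))
    m, d = positions.shape
    fitness = np.asarray(fitness, float)
    memories = positions.copy() if memories is None else np.atleast_2d(memories)
    memory_fitness = fitness.copy() if memory_fitness is None else np.asarray(memory_fitness, float)
    b = np.asarray(bounds, float)
    if len(b) == 1:
        b = np.repeat(b, d, axis=0)
    return hs.SwarmState(
        positions=positions,
        fitness=fitness,
        memories=memories,
        memory_fitness=memory_fitness,
        velocity=np.zeros(d) if velocity is None else np.asarray(velocity, float),
        bounds=b,
        rng=np.random.default_rng(seed),
    )


class TestInitialize:
    def test_seeded_determinism_and_bounds(self):
        cfg = hs.HybridSeekConfig(population_size=5, bounds=((0.0, 1.0),), seed=3)
        a = initialize(cfg, 2, sphere)
        b = initialize(cfg, 2, sphere)
        assert np.array_equal(a.positions, b.positions)
        assert a.positions.shape == (5, 2)
        assert np.all((a.positions >= 0) & (a.positions <= 1))

    def test_memory_equals_position_at_start(self):
        cfg = hs.HybridSeekConfig(population_size=4, bounds=((-1.0, 1.0),), seed=0)
        state = initialize(cfg, 3, sphere)
        assert np.array_equal(state.memories, state.positions)
        assert np.array_equal(state.memory_fitness, state.fitness)

    def test_single_agent_rejected(self):
        with pytest.raises(ParameterError):
            initialize(hs.HybridSeekConfig(population_size=1), 2, sphere)

    def test_non_finite_fitness_rejected(self):
        cfg = hs.HybridSeekConfig(population_size=3, bounds=((0.0, 1.0),), seed=0)
        with pytest.raises(EvaluationError):
            initialize(cfg, 2, lambda x: float("nan"))


class TestCorvidStep:
    def test_zero_lambda_is_identity(self):
        state = _state([[1.0, 2.0], [3.0, 4.0]], [0.0, 0.0])
        cfg = hs.HybridSeekConfig(population_size=2)
        out = corvid_step(0, state, cfg, followed_index=1, lam=0.0, aware=False)
        assert np.array_equal(out, [1.0, 2.0])

    def test_unit_step_lands_on_memory(self):
        state = _state([[0.0], [1.0]], [0.0, 0.0])
        cfg = hs.HybridSeekConfig(population_size=2, flight_length=1.0)
        out = corvid_step(0, state, cfg, followed_index=1, lam=1.0, aware=False)
        assert out[0] == pytest.approx(1.0)

    def test_flight_arithmetic(self):
        # J_e=2, Z_f=5, lam=0.5, a=2 -> 2 + 0.5*2*(5-2) = 5
        state = _state([[2.0], [5.0]], [0.0, 0.0])
        cfg = hs.HybridSeekConfig(population_size=2, flight_length=2.0)
        out = corvid_step(0, state, cfg, followed_index=1, lam=0.5, aware=False)
        assert out[0] == pytest.approx(5.0)

    def test_aware_branch_uniform_over_bounds(self):
        """With awareness certain, proposals are uniform in the box."""
        state = _state([[0.5], [0.5]], [0.0, 0.0], bounds=((0.0, 1.0),), seed=11)
        cfg = hs.HybridSeekConfig(population_size=2, awareness_probability=1.0)
        draws = np.array(
            [corvid_step(0, state, cfg, followed_index=1)[0] for _ in range(1000)]
        )
        assert np.all((draws >= 0) & (draws <= 1))
        assert stats.kstest(draws, "uniform").pvalue > 0.01


class TestGregariousStep:
    def test_non_best_fixed_point(self):
        """Agent sitting on the best position with zero velocity stays put."""
        state = _state([[1.0], [1.0]], [0.0, 5.0], memories=[[1.0], [1.0]],
                       memory_fitness=[0.0, 5.0])
        cfg = hs.HybridSeekConfig(population_size=2)
        out = gregarious_step(0, state, cfg, theta=0.7, nu1=0.0, varpi=0.0)
        assert out[0] == pytest.approx(1.0)

    def test_best_branch_repaired_quotient(self):
        # J=1, J_worst=0, chi=1, j_e - j_ws = 1, eps tiny -> ~2
        state = _state([[1.0], [0.0]], [1.0, 0.0])
        cfg = hs.HybridSeekConfig(population_size=2, epsilon=1e-12)
        out = gregarious_step(0, state, cfg, chi=1.0)
        assert out[0] == pytest.approx(2.0, abs=1e-9)

    def test_flat_fitness_no_blowup(self):
        state = _state([[1.0], [2.0]], [3.0, 3.0])
        cfg = hs.HybridSeekConfig(population_size=2, epsilon=1e-12)
        out = gregarious_step(0, state, cfg, chi=1.0)
        assert np.all(np.isfinite(out))


class TestHybridStep:
    def test_identical_inputs_fixed(self):
        v = np.array([1.0, -2.0])
        assert np.array_equal(hybrid_step(v, v), v)

    def test_midpoint(self):
        assert hybrid_step(np.array([0.0]), np.array([4.0]))[0] == 2.0

    def test_matches_independent_arithmetic(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.normal(size=(2, 6))
            np.testing.assert_allclose(hybrid_step(a, b), (a + b) / 2, rtol=1e-15)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            hybrid_step(np.zeros(2), np.zeros(3))


class TestFeasibilityAndMemory:
    def test_in_bounds_returned_unchanged(self):
        b = np.array([[0.0, 1.0]])
        p = np.array([0.5])
        assert clamp_feasible(p, b) is p

    def test_out_of_bounds_signals_infeasible(self):
        assert clamp_feasible(np.array([1.5]), np.array([[0.0, 1.0]])) is None

    def test_boundary_exact_is_feasible(self):
        b = np.array([[0.0, 1.0]])
        assert clamp_feasible(np.array([1.0]), b) is not None

    def test_memory_update_rules(self):
        state = _state([[1.0], [2.0]], [0.5, 0.2])
        state.positions[0] = np.array([9.0])
        assert not update_memory(state, 0, 0.4)      # worse: unchanged
        assert state.memories[0][0] == 1.0
        assert not update_memory(state, 0, 0.5)      # tie: unchanged
        assert update_memory(state, 0, 0.9)          # better: replaced
        assert state.memories[0][0] == 9.0
        assert state.memory_fitness[0] == 0.9


class TestOptimize:
    def test_sphere_convergence_single_seed(self):
        cfg = hs.HybridSeekConfig(
            population_size=30, max_iterations=200, bounds=((-5.0, 5.0),), seed=11
        )
        res = hs.optimize(sphere, 5, cfg)
        assert res.best_fitness >= -0.05
        assert np.all(np.abs(res.best_position) <= 0.2)

    def test_history_monotone_and_eval_count(self):
        cfg = hs.HybridSeekConfig(
            population_size=7, max_iterations=25, bounds=((-3.0, 3.0),), seed=5
        )
        res = hs.optimize(lambda x: float(np.sin(x).sum()), 4, cfg)
        hist = np.asarray(res.history)
        assert np.all(np.diff(hist) >= 0)
        assert res.best_fitness == hist[-1]
        assert res.n_evaluations == 7 * (25 + 1)

    def test_bit_identical_trajectories(self):
        cfg = hs.HybridSeekConfig(
            population_size=10, max_iterations=30, bounds=((-2.0, 2.0),), seed=123
        )
        r1 = hs.optimize(sphere, 3, cfg)
        r2 = hs.optimize(sphere, 3, cfg)
        assert r1.history == r2.history
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_beats_random_search_on_quadratics(self):
        """Median final error over seeds beats random search at equal budget."""
        errors_opt, errors_rand = [], []
        for seed in range(10):
            cfg = hs.HybridSeekConfig(
                population_size=15, max_iterations=40, bounds=((-5.0, 5.0),), seed=seed
            )
            res = hs.optimize(sphere, 4, cfg)
            errors_opt.append(-res.best_fitness)
            rng = np.random.default_rng(seed)
            draws = rng.uniform(-5, 5, size=(res.n_evaluations, 4))
            errors_rand.append(float(np.min(np.sum(draws**2, axis=1))))
        assert np.median(errors_opt) < np.median(errors_rand)

    def test_positions_stay_in_bounds(self):
        seen = []

        def recording_sphere(x):
            seen.append(np.array(x))
            return sphere(x)

        cfg = hs.HybridSeekConfig(
            population_size=6, max_iterations=20, bounds=((-1.0, 2.0),), seed=9
        )
        hs.optimize(recording_sphere, 3, cfg)
        arr = np.array(seen)
        assert np.all(arr >= -1.0) and np.all(arr <= 2.0)

    def test_non_finite_fitness_raises_with_position(self):
        def bad(x):
            return float("inf") if x[0] > 0 else -1.0

        cfg = hs.HybridSeekConfig(
            population_size=5, max_iterations=10, bounds=((-1.0, 1.0),), seed=2
        )
        with pytest.raises(EvaluationError):
            hs.optimize(bad, 2, cfg)

    def test_history_csv_export(self, tmp_path):
        cfg = hs.HybridSeekConfig(
            population_size=4, max_iterations=5, bounds=((-1.0, 1.0),), seed=0
        )
        res = hs.optimize(sphere, 2, cfg)
        path = tmp_path / "hist.csv"
        res.history_to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness"
        assert len(lines) == len(res.history) + 1
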