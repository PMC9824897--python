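"""Hybrid seek optimization.

A population metaheuristic that hybridizes two swarm update rules:

* a *corvid* (crow-search style) move, where each agent flies toward the
  memorized best position of a randomly followed flock-mate, unless that
  mate is "aware" (with probability ``awareness_probability``), in which
  case the follower relocates uniformly at random inside the bounds; and
* a *gregarious* (sparrow-search style) move, where non-best agents are
  drawn toward the global best position (augmented by a swarm velocity
  term) and the current best agent explores relative to the worst agent.

Each agent's proposal is the elementwise midpoint of its corvid and
gregarious proposals.  Out-of-bounds proposals are rejected and the old
position kept (no clipping).  Per-agent memories record the best position
ever held, so the best-so-far fitness is monotonically non-decreasing.

Fitness is **maximized** and must be finite and deterministic given the
position.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import EvaluationError, ParameterError

__all__ = [
    "HybridSeekConfig",
    "SwarmState",
    "OptimizationResult",
    "initialize",
    "corvid_step",
    "gregarious_step",
    "hybrid_step",
    "clamp_feasible",
    "update_memory",
    "optimize",
]

FitnessFunction = Callable[[np.ndarray], float]


@dataclass
class HybridSeekConfig:
    """Hyper-parameters of the hybrid seek optimizer.

    Parameters
    ----------
    population_size : int
        Flock size ``m`` (at least 2).
    max_iterations : int
        Number of position-update sweeps after initialization.
    flight_length : float
        Step-length multiplier of the corvid move.
    awareness_probability : float in [0, 1]
        Probability that a followed agent is aware, sending the follower
        to a uniform random position.
    bounds : sequence of (lo, hi)
        Per-dimension box bounds; a single pair is broadcast to every
        dimension at :func:`optimize` time.
    epsilon : float
        Small positive guard added to the fitness-spread denominator of
        the best agent's gregarious move.
    seed : int or None
        Seed for all random draws.
    """

    population_size: int = 25
    max_iterations: int = 100
    flight_length: float = 2.0
    awareness_probability: float = 0.1
    bounds: Sequence[tuple[float, float]] = ((0.0, 1.0),)
    epsilon: float = 1e-12
    seed: int | None = None

    def validate(self) -> None:
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if not 0.0 <= self.awareness_probability <= 1.0:
            raise ParameterError("awareness_probability must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ParameterError(f"invalid bound ({lo}, {hi}): need lo < hi")

    def bounds_array(self, dimension: int) -> np.ndarray:
        """Bounds as a (dimension, 2) array, broadcasting a single pair."""
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ParameterError("bounds must be a sequence of (lo, hi) pairs")
        if len(b) == 1:
            b = np.repeat(b, dimension, axis=0)
        if len(b) != dimension:
            raise ParameterError(
                f"got {len(b)} bound pairs for dimension {dimension}"
            )
        return b


@dataclass
class SwarmState:
    """Mutable swarm state: positions, memories, velocity and bookkeeping."""

    positions: np.ndarray       # (m, D) current positions
    fitness: np.ndarray         # (m,) fitness of current positions
    memories: np.ndarray        # (m, D) best position each agent has held
    memory_fitness: np.ndarray  # (m,)
    velocity: np.ndarray        # (D,) swarm-global velocity term
    bounds: np.ndarray          # (D, 2)
    rng: np.random.Generator
    iteration: int = 0
    n_evaluations: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.memory_fitness))

    @property
    def best_position(self) -> np.ndarray:
        return self.memories[self.best_index]

    @property
    def best_fitness(self) -> float:
        """Global best fitness (over memories)."""
        return float(self.memory_fitness[self.best_index])

    @property
    def worst_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def worst_position(self) -> np.ndarray:
        return self.positions[self.worst_index]

    @property
    def worst_fitness(self) -> float:
        """Global worst fitness (over current positions)."""
        return float(self.fitness[self.worst_index])


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def history_to_csv(self, path) -> None:
        """Write the convergence history as (iteration, best_fitness) CSV."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "best_fitness"])
            for i, v in enumerate(self.history):
                writer.writerow([i, repr(v)])


def _evaluate(fitness: FitnessFunction, position: np.ndarray) -> float:
    value = float(fitness(position))
    if not np.isfinite(value):
        raise EvaluationError(
            f"fitness returned non-finite value {value!r} at position "
            f"{np.array2string(position, precision=6)}"
        )
    return value


def initialize(
    config: HybridSeekConfig,
    dimension: int,
    fitness: FitnessFunction,
) -> SwarmState:
    """Place agents uniformly in the bounds; memory starts at the position."""
    config.validate()
    if dimension < 1:
        raise ParameterError("dimension must be >= 1")
    bounds = config.bounds_array(dimension)
    rng = np.random.default_rng(config.seed)
    m = config.population_size
    positions = rng.uniform(bounds[:, 0], bounds[:, 1], size=(m, dimension))
    values = np.array([_evaluate(fitness, p) for p in positions])
    state = SwarmState(
        positions=positions,
        fitness=values,
        memories=positions.copy(),
        memory_fitness=values.copy(),
        velocity=np.zeros(dimension),
        bounds=bounds,
        rng=rng,
    )
    state.n_evaluations = m
    return state


def corvid_step(
    agent_index: int,
    state: SwarmState,
    config: HybridSeekConfig,
    *,
    followed_index: int | None = None,
    lam: float | None = None,
    aware: bool | None = None,
) -> np.ndarray:
    """Crow-style proposal for one agent.

    The agent follows a random flock-mate ``f``; if ``f`` is unaware the
    proposal is ``J_e + lam * a * (Z_f - J_e)``, otherwise the follower
    evades to a uniform random position inside the bounds.  The keyword
    overrides exist for deterministic testing; by default every draw
    comes from the swarm RNG.
    """
    rng = state.rng
    m = len(state.positions)
    if followed_index is None:
        followed_index = int(rng.integers(m - 1))
        if followed_index >= agent_index:
            followed_index += 1
    if aware is None:
        aware = bool(rng.random() < config.awareness_probability)
    if lam is None:
        lam = float(rng.random())
    if aware:
        return rng.uniform(state.bounds[:, 0], state.bounds[:, 1])
    position = state.positions[agent_index]
    memory = state.memories[followed_index]
    return position + lam * config.flight_length * (memory - position)


def gregarious_step(
    agent_index: int,
    state: SwarmState,
    config: HybridSeekConfig,
    *,
    theta: float | None = None,
    chi: float | None = None,
    nu1: float | None = None,
    varpi: float | None = None,
) -> np.ndarray:
    """Sparrow-style proposal for one agent.

    Non-best agents move toward the global best position augmented by the
    swarm velocity; the (tied-)best agent explores relative to the worst
    agent, with the fitness spread in the denominator guarded by epsilon.
    """
    rng = state.rng
    j_e = float(state.fitness[agent_index])
    position = state.positions[agent_index]
    j_gl = state.best_fitness
    if j_e >= j_gl:  # this agent currently matches the global best
        if chi is None:
            chi = float(rng.uniform(-1.0, 1.0))
        spread = (j_e - state.worst_fitness) + config.epsilon
        return position + chi * np.abs(position - state.worst_position) / spread
    if theta is None:
        theta = float(rng.random())
    if nu1 is None:
        nu1 = float(rng.random())
    if varpi is None:
        varpi = float(rng.random())
    best = state.best_position
    return best + theta * np.abs(
        position - best * (1.0 + nu1 * varpi) + state.velocity
    )


def hybrid_step(corvid_pos: np.ndarray, gregarious_pos: np.ndarray) -> np.ndarray:
    """Equal-weight combination of the two proposals (elementwise midpoint)."""
    corvid_pos = np.asarray(corvid_pos, dtype=float)
    gregarious_pos = np.asarray(gregarious_pos, dtype=float)
    if corvid_pos.shape != gregarious_pos.shape:
        raise ParameterError(
            f"dimension mismatch: {corvid_pos.shape} vs {gregarious_pos.shape}"
        )
    return 0.5 * corvid_pos + 0.5 * gregarious_pos


def clamp_feasible(position: np.ndarray, bounds: np.ndarray) -> np.ndarray | None:
    """Return the proposal if inside the (closed) bounds, else ``None``.

    ``None`` signals infeasibility: the caller keeps the old position
    rather than clipping the proposal to the box.
    """
    bounds = np.asarray(bounds, dtype=float)
    if np.all(position >= bounds[:, 0]) and np.all(position <= bounds[:, 1]):
        return position
    return None


def update_memory(state: SwarmState, agent_index: int, new_fitness: float) -> bool:
    """Replace the agent's memory iff the new fitness strictly improves it."""
    if new_fitness > state.memory_fitness[agent_index]:
        state.memories[agent_index] = state.positions[agent_index]
        state.memory_fitness[agent_index] = new_fitness
        return True
    return False


def optimize(
    fitness: FitnessFunction,
    dimension: int,
    config: HybridSeekConfig,
) -> OptimizationResult:
    """Run the full hybrid seek loop and return the best memory found.

    Each of ``max_iterations`` sweeps proposes, for every agent, the
    midpoint of a corvid and a gregarious move, keeps the old position if
    the proposal leaves the box, evaluates, and updates the agent memory
    on strict improvement.  The swarm velocity is refreshed once per sweep.
    Identical ``(config, seed, fitness)`` give bit-identical trajectories.
    """
    state = initialize(config, dimension, fitness)
    history = [state.best_fitness]
    for n in range(config.max_iterations):
        state.iteration = n + 1
        nu_v = state.rng.random()
        varpi_v = state.rng.random()
        state.velocity = state.velocity + nu_v * varpi_v * state.best_position
        for e in range(config.population_size):
            c_pos = corvid_step(e, state, config)
            g_pos = gregarious_step(e, state, config)
            proposal = hybrid_step(c_pos, g_pos)
            accepted = clamp_feasible(proposal, state.bounds)
            if accepted is not None:
                state.positions[e] = accepted
            value = _evaluate(fitness, state.positions[e])
            state.n_evaluations += 1
            state.fitness[e] = value
            update_memory(state, e, value)
        history.append(state.best_fitness)
    return OptimizationResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=history,
        n_evaluations=state.n_evaluations,
    )
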