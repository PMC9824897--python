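"""Run the hybrid seek optimizer on a 5-D sphere benchmark.

Maximizing f(x) = -sum(x^2) over [-5, 5]^5 has its optimum at the origin;
the printed best position should be within ~0.2 of it in every coordinate
and the best-so-far history is non-decreasing by construction (memory
elitism).
"""

import numpy as np

import hybridseek as hs


def sphere(x):
    return float(-np.sum(x**2))


config = hs.HybridSeekConfig(
    population_size=30, max_iterations=200, bounds=((-5.0, 5.0),), seed=11
)
result = hs.optimize(sphere, dimension=5, config=config)

print(f"best fitness: {result.best_fitness:.6f} (optimum 0)")
print("best position:", np.array2string(result.best_position, precision=4))
print(f"function evaluations: {result.n_evaluations}")
hist = np.asarray(result.history)
print(f"history monotone non-decreasing: {bool(np.all(np.diff(hist) >= 0))}")
print("best-so-far at iterations 0/50/100/200:",
      [round(float(hist[i]), 4) for i in (0, 50, 100, 200)])
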