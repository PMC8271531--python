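"""Continuous Whale Optimization Algorithm (WOA).

WOA is a population-based metaheuristic mimicking the bubble-net hunting of
humpback whales.  Each search agent (whale) holds a real-valued position
``X`` in the decision space; the incumbent best solution ``X*`` plays the
role of the prey.  Per iteration each whale applies one of three operators:

* **shrinking encirclement** — move toward ``X*``:
  ``X(t+1) = X* − A ⊙ |C ⊙ X* − X|``;
* **spiral update** — approach ``X*`` along a logarithmic spiral:
  ``X(t+1) = |X* − X| · e^{b·l} · cos(2πl) + X*``;
* **random search** — move relative to a randomly chosen peer ``X_rand``
  instead of ``X*`` (exploration).

The coefficient ``a`` decreases linearly from 2 to 0 over the run, which
shifts the swarm from exploration (|A| ≥ 1) to exploitation (|A| < 1).  The
spiral branch is taken with probability 1/2 (the random draw ``p``).

Minimization convention throughout; negate the objective to maximize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import DimensionMismatchError, EvaluationError

Objective = Callable[[np.ndarray], float]

__all__ = [
    "SearchAgent",
    "WOAConfig",
    "WOAState",
    "StepCoefficients",
    "linear_decrease_a",
    "draw_coefficients",
    "encircle_update",
    "spiral_update",
    "random_search_update",
    "step",
    "optimize",
]


@dataclass
class SearchAgent:
    """One whale: a position vector and its objective value."""

    position: np.ndarray
    fitness: float = math.inf

    def copy(self) -> "SearchAgent":
        return SearchAgent(self.position.copy(), self.fitness)


@dataclass
class WOAConfig:
    """Run parameters for the WOA loop.

    Parameters
    ----------
    population_size:
        Number of whales (≥ 2).  Default 10 — a common desk-scale setting
        for wrapper feature selection.
    max_iterations:
        Number of position-update sweeps T_max (≥ 1).  Default 100.
    spiral_constant:
        Shape parameter ``b`` of the logarithmic spiral.  Default 1.
    seed:
        Seed for the run's random stream; identical (seed, config,
        objective) triples reproduce trajectories bit for bit.
    bounds:
        Optional per-dimension ``(lower, upper)`` pairs.  When present,
        positions are clamped into the box after every update; when absent
        the search is unconstrained (agents are still initialized inside a
        default hypercube).
    """

    population_size: int = 10
    max_iterations: int = 100
    spiral_constant: float = 1.0
    seed: int = 0
    bounds: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.bounds is not None:
            for d, (lo, hi) in enumerate(self.bounds):
                if not lo < hi:
                    raise ValueError(
                        f"bounds[{d}]: lower ({lo}) must be < upper ({hi})"
                    )


@dataclass
class WOAState:
    """Snapshot of the optimization loop after ``iteration`` sweeps."""

    iteration: int
    population: list[SearchAgent]
    best: SearchAgent
    a: float


@dataclass
class StepCoefficients:
    """The per-agent random coefficients of one position update.

    ``A`` and ``C`` are per-dimension vectors with ``A = 2a·r − a`` (each
    component in [−a, a]) and ``C = 2·r'`` (each component in [0, 2]);
    ``l`` is uniform on [−1, 1] and steers the spiral; ``p`` is uniform on
    [0, 1] and chooses between the spiral and the encircling branch.
    """

    A: np.ndarray
    C: np.ndarray
    l: float
    p: float


def linear_decrease_a(t: int, t_max: int) -> float:
    """Coefficient ``a`` at iteration ``t``: linear ramp from 2 down to 0.

    Exactly 2 at ``t = 0`` and exactly 0 at ``t = t_max``.
    """
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")
    return 2.0 * (1.0 - t / t_max)


def draw_coefficients(
    a: float, dimension: int, rng: np.random.Generator
) -> StepCoefficients:
    """Draw one agent's step coefficients.

    Fresh uniform draws ``r, r'`` per dimension give ``A = 2a·r − a`` and
    ``C = 2·r'``; ``l ~ U[−1, 1]`` and ``p ~ U[0, 1]`` are scalars.
    """
    r = rng.random(dimension)
    r2 = rng.random(dimension)
    A = 2.0 * a * r - a
    C = 2.0 * r2
    l = rng.uniform(-1.0, 1.0)
    p = rng.random()
    return StepCoefficients(A=A, C=C, l=l, p=p)


def _check_dims(*vectors: np.ndarray) -> None:
    dims = {v.shape for v in vectors}
    if len(dims) > 1:
        raise DimensionMismatchError(f"mismatched vector shapes: {sorted(dims)}")


def encircle_update(
    x: np.ndarray, x_best: np.ndarray, A: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Shrinking-encirclement move toward the incumbent best.

    Returns ``X* − A ⊙ |C ⊙ X* − X|`` (elementwise).  With ``A = 0`` the
    agent lands exactly on ``X*``.
    """
    _check_dims(x, x_best, A, C)
    d = np.abs(C * x_best - x)
    return x_best - A * d


def spiral_update(
    x: np.ndarray, x_best: np.ndarray, b: float, l: float
) -> np.ndarray:
    """Logarithmic-spiral move around the incumbent best.

    Returns ``|X* − X| · e^{b·l} · cos(2πl) + X*`` with the whale-to-prey
    distance taken elementwise; ``l = −1`` is the closest approach.
    """
    _check_dims(x, x_best)
    d_prime = np.abs(x_best - x)
    return d_prime * math.exp(b * l) * math.cos(2.0 * math.pi * l) + x_best


def random_search_update(
    x: np.ndarray, x_rand: np.ndarray, A: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Exploration move relative to a randomly chosen peer.

    Returns ``X_rand − A ⊙ |C ⊙ X_rand − X|``.
    """
    _check_dims(x, x_rand, A, C)
    d = np.abs(C * x_rand - x)
    return x_rand - A * d


def _clamp(x: np.ndarray, bounds: Sequence[tuple[float, float]] | None) -> np.ndarray:
    if bounds is None:
        return x
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def step(
    state: WOAState,
    objective: Objective,
    config: WOAConfig,
    rng: np.random.Generator,
) -> WOAState:
    """Advance the swarm by one iteration.

    For each agent: draw coefficients; with ``p < 0.5`` encircle the best
    when ``|A| < 1`` (first component) or search toward a random peer when
    ``|A| ≥ 1``; with ``p ≥ 0.5`` take the spiral branch.  New positions are
    clamped to bounds when configured, re-evaluated, and the incumbent best
    is updated immediately (elitist: the best fitness never increases).
    """
    a = linear_decrease_a(state.iteration, config.max_iterations)
    dim = state.best.position.shape[0]
    best = state.best.copy()
    new_population: list[SearchAgent] = []
    for i, agent in enumerate(state.population):
        coeffs = draw_coefficients(a, dim, rng)
        if coeffs.p < 0.5:
            if abs(coeffs.A[0]) < 1.0:
                pos = encircle_update(agent.position, best.position, coeffs.A, coeffs.C)
            else:
                j = int(rng.integers(len(state.population)))
                pos = random_search_update(
                    agent.position, state.population[j].position, coeffs.A, coeffs.C
                )
        else:
            pos = spiral_update(
                agent.position, best.position, config.spiral_constant, coeffs.l
            )
        pos = _clamp(pos, config.bounds)
        fit = float(objective(pos))
        if not math.isfinite(fit):
            raise EvaluationError(
                f"objective returned non-finite value {fit!r} for agent {i}"
            )
        moved = SearchAgent(pos, fit)
        new_population.append(moved)
        if fit < best.fitness:
            best = moved.copy()
    next_t = state.iteration + 1
    return WOAState(
        iteration=next_t,
        population=new_population,
        best=best,
        a=linear_decrease_a(min(next_t, config.max_iterations), config.max_iterations),
    )


def _initial_state(
    objective: Objective, dimension: int, config: WOAConfig, rng: np.random.Generator
) -> WOAState:
    if config.bounds is not None:
        lo = np.array([b[0] for b in config.bounds], dtype=float)
        hi = np.array([b[1] for b in config.bounds], dtype=float)
    else:
        # default init hypercube; the search itself stays unconstrained
        lo = np.full(dimension, -1.0)
        hi = np.full(dimension, 1.0)
    population = []
    best: SearchAgent | None = None
    for i in range(config.population_size):
        pos = rng.uniform(lo, hi)
        fit = float(objective(pos))
        if not math.isfinite(fit):
            raise EvaluationError(
                f"objective returned non-finite value {fit!r} for agent {i}"
            )
        agent = SearchAgent(pos, fit)
        population.append(agent)
        if best is None or fit < best.fitness:
            best = agent.copy()
    assert best is not None
    return WOAState(iteration=0, population=population, best=best, a=2.0)


def optimize(
    objective: Objective, dimension: int, config: WOAConfig
) -> tuple[SearchAgent, list[float]]:
    """Run the full WOA loop.

    Initializes ``population_size`` whales uniformly inside the bounds (or
    a default hypercube), performs ``max_iterations`` steps, and returns the
    best agent together with the best-fitness trace — one entry after
    initialization plus one per iteration (length ``max_iterations + 1``),
    non-increasing by elitism.
    """
    if dimension < 1:
        raise ValueError("dimension must be at least 1")
    if config.bounds is not None and len(config.bounds) != dimension:
        raise DimensionMismatchError(
            f"bounds has {len(config.bounds)} entries for dimension {dimension}"
        )
    rng = np.random.default_rng(config.seed)
    state = _initial_state(objective, dimension, config, rng)
    history = [state.best.fitness]
    for _ in range(config.max_iterations):
        state = step(state, objective, config, rng)
        history.append(state.best.fitness)
    return state.best, history
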