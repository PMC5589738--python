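"""Population metaheuristics for bound-constrained continuous minimization.

The primary algorithm is the whale optimization algorithm (WOA): each agent
either (a) spirals toward the best-so-far position, (b) moves toward the best
position ("encircling") when its scalar coefficient ``|A|`` is below the
exploration threshold, or (c) moves relative to a randomly chosen agent
otherwise.  The coefficient scale ``a`` decreases linearly from 2 to 0 over
the run.  Update rules::

    D = |C * X_ref - X|
    X_new = X_ref - A * D               (encircle / explore)
    X_new = |X* - X| * exp(b*l) * cos(2*pi*l) + X*    (spiral)

with ``A = 2*a*r - a`` (one scalar draw per agent per iteration, broadcast
across dimensions) and ``C = 2*r`` (per-dimension draws).  Positions are
hard-clipped to the box after every update and the best solution is tracked
elitistly, so the best-fitness trace is nonincreasing.

Global-best PSO and a real-coded GA (tournament selection, blend crossover,
Gaussian mutation) are provided behind the same interface as baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "WOAConfig",
    "OptimizerResult",
    "init_population",
    "coefficients",
    "encircle_update",
    "spiral_update",
    "explore_update",
    "woa_step",
    "woa_minimize",
    "pso_minimize",
    "ga_minimize",
    "minimize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObjectiveSpec:
    """A scalar objective (lower is better) over a box-bounded domain."""

    fn: Callable[[np.ndarray], float]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if np.any(lo >= hi):
            raise ValueError("every lower bound must be < its upper bound")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    def evaluate(self, x: np.ndarray) -> float:
        """Evaluate, mapping non-finite results to +inf (never selected)."""
        value = float(self.fn(x))
        if not np.isfinite(value):
            logger.debug("objective returned non-finite value; treating as +inf")
            return np.inf
        return value

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class WOAConfig:
    """WOA settings (also reused for the PSO/GA baselines' shared fields)."""

    n: int = 25
    max_iter: int = 100
    b: float = 1.0                 # logarithmic spiral shape constant
    tau_a: float = 1.0             # exploration threshold on |A|
    seed: int = 0
    stop_tol: float | None = None  # stop early when best fitness <= this

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tau_a > 0:
            raise ValueError("tau_a must be > 0")


@dataclass(frozen=True)
class OptimizerResult:
    """Best solution found plus the per-iteration best-fitness trace."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    n_evaluations: int


@dataclass
class _State:
    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    n_evaluations: int = 0


def init_population(
    spec: ObjectiveSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform random positions within the box, ``n x dim``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(spec.lower, spec.upper, size=(n, spec.dim))


def coefficients(a: float, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient pair ``A = 2*a*r - a`` and ``C = 2*r`` for draws r in [0,1]."""
    r = np.asarray(r, dtype=float)
    return 2.0 * a * r - a, 2.0 * r


def encircle_update(x, x_best, A, C) -> np.ndarray:
    """Move toward the best position: ``x_best - A * |C*x_best - x|``."""
    d = np.abs(np.asarray(C) * np.asarray(x_best) - np.asarray(x))
    return np.asarray(x_best) - np.asarray(A) * d


def spiral_update(x, x_best, b: float, l: float) -> np.ndarray:
    """Logarithmic-spiral move: ``|x_best - x| * e^(b*l) * cos(2*pi*l) + x_best``."""
    d = np.abs(np.asarray(x_best) - np.asarray(x))
    return d * np.exp(b * l) * np.cos(2.0 * np.pi * l) + np.asarray(x_best)


def explore_update(x, x_rand, A, C) -> np.ndarray:
    """Move relative to a random agent: ``x_rand - A * |C*x_rand - x|``."""
    d = np.abs(np.asarray(C) * np.asarray(x_rand) - np.asarray(x))
    return np.asarray(x_rand) - np.asarray(A) * d


def woa_step(
    state: _State,
    spec: ObjectiveSpec,
    config: WOAConfig,
    rng: np.random.Generator,
    a: float,
) -> _State:
    """Advance every agent one iteration at coefficient scale ``a``.

    Per-agent random draw order: ``p`` uniform [0,1]; if ``p >= 0.5`` a
    spiral parameter ``l`` uniform [-1,1]; otherwise a scalar draw for ``A``,
    a per-dimension draw vector for ``C``, and (exploring only) a random
    agent index.
    """
    n, dim = state.positions.shape
    new_positions = np.empty_like(state.positions)
    for i in range(n):
        x = state.positions[i]
        p = rng.random()
        if p >= 0.5:
            l = rng.uniform(-1.0, 1.0)
            x_new = spiral_update(x, state.best_position, config.b, l)
        else:
            A_scalar, _ = coefficients(a, rng.random())
            _, C = coefficients(a, rng.random(dim))
            if abs(A_scalar) < config.tau_a:
                x_new = encircle_update(x, state.best_position, A_scalar, C)
            else:
                j = int(rng.integers(n))
                x_new = explore_update(x, state.positions[j], A_scalar, C)
        new_positions[i] = spec.clip(x_new)

    fitness = np.array([spec.evaluate(x) for x in new_positions])
    state.positions = new_positions
    state.fitness = fitness
    state.n_evaluations += n
    i_best = int(np.argmin(fitness))
    if fitness[i_best] < state.best_fitness:
        state.best_fitness = float(fitness[i_best])
        state.best_position = new_positions[i_best].copy()
    return state


def _init_state(
    spec: ObjectiveSpec,
    config: WOAConfig,
    rng: np.random.Generator,
    initial_positions: Sequence[np.ndarray] | None,
) -> _State:
    positions = init_population(spec, config.n, rng)
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        if seeds.shape[0] > config.n:
            raise ValueError("more seed positions than population members")
        positions[: seeds.shape[0]] = spec.clip(seeds)
    fitness = np.array([spec.evaluate(x) for x in positions])
    i_best = int(np.argmin(fitness))
    if not np.isfinite(fitness[i_best]):
        raise RuntimeError("all initial fitness values are non-finite")
    return _State(
        positions=positions,
        fitness=fitness,
        best_position=positions[i_best].copy(),
        best_fitness=float(fitness[i_best]),
        n_evaluations=config.n,
    )


def woa_minimize(
    spec: ObjectiveSpec,
    config: WOAConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> OptimizerResult:
    """Run WOA to ``max_iter`` iterations (or until ``stop_tol`` is reached).

    ``initial_positions`` optionally replaces the first rows of the random
    initial population (used to inject a clustering-derived warm start).
    """
    rng = np.random.default_rng(config.seed)
    state = _init_state(spec, config, rng, initial_positions)
    trace = []
    for t in range(1, config.max_iter + 1):
        a = 2.0 * (1.0 - t / config.max_iter)
        woa_step(state, spec, config, rng, a)
        trace.append(state.best_fitness)
        if config.stop_tol is not None and state.best_fitness <= config.stop_tol:
            break
    return OptimizerResult(
        best_position=state.best_position,
        best_fitness=state.best_fitness,
        trace=np.asarray(trace),
        n_evaluations=state.n_evaluations,
    )


def pso_minimize(
    spec: ObjectiveSpec,
    config: WOAConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> OptimizerResult:
    """Global-best particle swarm (constriction coefficients)."""
    w, c1, c2 = 0.729, 1.49445, 1.49445
    rng = np.random.default_rng(config.seed)
    state = _init_state(spec, config, rng, initial_positions)
    n, dim = state.positions.shape
    span = spec.upper - spec.lower
    velocity = rng.uniform(-span, span, size=(n, dim)) * 0.1
    pbest = state.positions.copy()
    pbest_fit = state.fitness.copy()
    trace = []
    for _ in range(config.max_iter):
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        velocity = (
            w * velocity
            + c1 * r1 * (pbest - state.positions)
            + c2 * r2 * (state.best_position[None, :] - state.positions)
        )
        state.positions = spec.clip(state.positions + velocity)
        state.fitness = np.array([spec.evaluate(x) for x in state.positions])
        state.n_evaluations += n
        improved = state.fitness < pbest_fit
        pbest[improved] = state.positions[improved]
        pbest_fit[improved] = state.fitness[improved]
        i_best = int(np.argmin(pbest_fit))
        if pbest_fit[i_best] < state.best_fitness:
            state.best_fitness = float(pbest_fit[i_best])
            state.best_position = pbest[i_best].copy()
        trace.append(state.best_fitness)
        if config.stop_tol is not None and state.best_fitness <= config.stop_tol:
            break
    return OptimizerResult(
        best_position=state.best_position,
        best_fitness=state.best_fitness,
        trace=np.asarray(trace),
        n_evaluations=state.n_evaluations,
    )


def ga_minimize(
    spec: ObjectiveSpec,
    config: WOAConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> OptimizerResult:
    """Real-coded GA: tournament selection, blend crossover, Gaussian mutation."""
    tournament_k, blend_alpha, mut_sd_frac = 3, 0.5, 0.1
    rng = np.random.default_rng(config.seed)
    state = _init_state(spec, config, rng, initial_positions)
    n, dim = state.positions.shape
    span = spec.upper - spec.lower
    p_mut = 1.0 / dim
    trace = []

    def tournament() -> np.ndarray:
        idx = rng.integers(n, size=tournament_k)
        return state.positions[idx[np.argmin(state.fitness[idx])]]

    for _ in range(config.max_iter):
        children = np.empty_like(state.positions)
        children[0] = state.best_position         # elitism
        for i in range(1, n):
            pa, pb = tournament(), tournament()
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            width = hi - lo
            child = rng.uniform(lo - blend_alpha * width, hi + blend_alpha * width)
            mutate = rng.random(dim) < p_mut
            child = child + mutate * rng.normal(0.0, mut_sd_frac * span, size=dim)
            children[i] = child
        state.positions = spec.clip(children)
        state.fitness = np.array([spec.evaluate(x) for x in state.positions])
        state.n_evaluations += n
        i_best = int(np.argmin(state.fitness))
        if state.fitness[i_best] < state.best_fitness:
            state.best_fitness = float(state.fitness[i_best])
            state.best_position = state.positions[i_best].copy()
        trace.append(state.best_fitness)
        if config.stop_tol is not None and state.best_fitness <= config.stop_tol:
            break
    return OptimizerResult(
        best_position=state.best_position,
        best_fitness=state.best_fitness,
        trace=np.asarray(trace),
        n_evaluations=state.n_evaluations,
    )


_MINIMIZERS = {"woa": woa_minimize, "pso": pso_minimize, "ga": ga_minimize}


def minimize(
    name: str,
    spec: ObjectiveSpec,
    config: WOAConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> OptimizerResult:
    """Dispatch to one of the registered algorithms: 'woa', 'pso', 'ga'."""
    try:
        fn = _MINIMIZERS[name]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_MINIMIZERS)}")
    return fn(spec, config, initial_positions=initial_positions)
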