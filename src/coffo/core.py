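"""Continuous-space fruit fly optimization: the plain driver (FFO) and the
chaotic oppositional variant (COFFO).

The fruit fly algorithm is a swarm method with two phases per iteration: an
*osphresis* (smell) phase, in which every member takes a uniform random step
from its current location, and a *vision* phase, in which the whole swarm
relocates to the best position found so far whenever that best improved.
COFFO keeps this skeleton and adds (a) a chaotic-opposition initialization
that evaluates 2N candidates and keeps the fittest N, and (b) a chaotic
local search (CLS) around the global best, triggered once a configurable
share of the evaluation budget has been spent.

The computational budget is counted in fitness function evaluations (FFEs);
the budget counter is the sole termination authority.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import as_generator, substream
from .errors import BudgetExhausted, InvalidArgument, InvalidConfiguration

__all__ = [
    "Bounds",
    "Solution",
    "Population",
    "BudgetCounter",
    "OptimizerConfig",
    "OptimizationResult",
    "init_random_population",
    "osphresis_step",
    "vision_update",
    "run_ffo",
    "run_coffo",
]


@dataclass(frozen=True)
class Bounds:
    """A box constraint: per-dimension lower and upper limits."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise InvalidArgument("lower and upper must be 1-D vectors of equal length")
        if lower.size < 1:
            raise InvalidArgument("dimension must be >= 1")
        if not np.all(lower < upper):
            raise InvalidArgument("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def box(cls, low: float, high: float, dimension: int) -> "Bounds":
        """Symmetric box ``[low, high]^dimension``."""
        if dimension < 1:
            raise InvalidArgument("dimension must be >= 1")
        return cls(np.full(dimension, low), np.full(dimension, high))

    @property
    def dimension(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass
class Solution:
    """A candidate position, optionally with its objective value attached."""

    position: np.ndarray
    fitness: Optional[float] = None

    def copy(self) -> "Solution":
        return Solution(self.position.copy(), self.fitness)


@dataclass
class Population:
    """N candidate positions with (possibly unset = NaN) fitness values."""

    positions: np.ndarray  # (n, d)
    fitness: np.ndarray  # (n,), NaN where unset

    @classmethod
    def empty_fitness(cls, positions: np.ndarray) -> "Population":
        return cls(positions, np.full(positions.shape[0], np.nan))

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def best_index(self) -> int:
        if np.all(np.isnan(self.fitness)):
            raise InvalidArgument("population has no evaluated member")
        return int(np.nanargmin(self.fitness))


@dataclass
class BudgetCounter:
    """FFE accounting: ``used`` never exceeds ``limit``."""

    limit: int
    used: int = 0

    def __post_init__(self):
        if self.limit < 1:
            raise InvalidArgument("budget limit must be positive")
        if not 0 <= self.used <= self.limit:
            raise InvalidArgument("used must lie in [0, limit]")

    @property
    def remaining(self) -> int:
        return self.limit - self.used

    @property
    def exhausted(self) -> bool:
        return self.used >= self.limit

    def spend(self) -> None:
        if self.exhausted:
            raise BudgetExhausted(f"FFE budget of {self.limit} exhausted")
        self.used += 1


@dataclass(frozen=True)
class OptimizerConfig:
    """Control parameters shared by FFO and COFFO.

    ``cls_trigger=None`` resolves to ``max_ffes // 3``, the empirical rule
    used for the benchmark experiments (25,050 // 3 = 8,350).
    """

    population_size: int = 50
    max_ffes: int = 25_050
    cls_steps: int = 4
    cls_trigger: Optional[int] = None
    chaos_mu: float = 4.0
    step_scale: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.population_size < 1:
            raise InvalidConfiguration("population_size must be positive")
        if self.max_ffes < 1:
            raise InvalidConfiguration("max_ffes must be positive")
        if self.cls_steps < 1:
            raise InvalidConfiguration("cls_steps must be positive")
        if self.step_scale <= 0:
            raise InvalidConfiguration("step_scale must be positive")
        trigger = self.max_ffes // 3 if self.cls_trigger is None else self.cls_trigger
        if not 0 <= trigger <= self.max_ffes:
            raise InvalidConfiguration("cls_trigger must lie in [0, max_ffes]")
        object.__setattr__(self, "cls_trigger", int(trigger))

    @classmethod
    def benchmark_defaults(cls, population_size: int = 50, max_iter: int = 500,
                           **kwargs) -> "OptimizerConfig":
        """Budget rule maxFFEs = N + N*maxIter (25,050 at the defaults)."""
        return cls(population_size=population_size,
                   max_ffes=population_size + population_size * max_iter, **kwargs)


@dataclass
class OptimizationResult:
    """Best solution found plus the best-so-far trace (FFE, fitness) pairs."""

    best_position: np.ndarray
    best_fitness: float
    trace: list = field(default_factory=list)
    ffes_used: int = 0


def init_random_population(bounds: Bounds, n: int, rng) -> Population:
    """Uniform random positions in the box; fitness unset."""
    if n < 1:
        raise InvalidArgument("population size must be >= 1")
    rng = as_generator(rng)
    span = bounds.upper - bounds.lower
    positions = bounds.lower + rng.random((n, bounds.dimension)) * span
    return Population.empty_fitness(positions)


def osphresis_step(current: Solution, bounds: Bounds, step_scale: float, rng) -> np.ndarray:
    """Random-walk candidate: current + step_scale * U[-1, 1] per component,
    clamped to the box. The signed uniform draw absorbs the +/- of the
    textbook update rule."""
    rng = as_generator(rng)
    u = rng.uniform(-1.0, 1.0, size=bounds.dimension)
    return bounds.clamp(current.position + step_scale * u)


def vision_update(population: Population, best: Solution, improved: bool = True) -> Population:
    """Vision phase: if this iteration improved the global best, the whole
    swarm relocates to the best position; otherwise nothing changes."""
    if best.fitness is None:
        raise InvalidArgument("best solution must be evaluated")
    if improved:
        population.positions[:] = best.position
        population.fitness[:] = best.fitness
    return population


class _Tracker:
    """Best-so-far bookkeeping with a monotone (FFE, fitness) trace.

    Strictly-better comparison: ties keep the incumbent.
    """

    def __init__(self):
        self.best: Optional[Solution] = None
        self.trace: list = []

    def offer(self, position: np.ndarray, fitness: float, ffe: int) -> bool:
        if self.best is None or fitness < self.best.fitness:
            self.best = Solution(np.array(position, dtype=float, copy=True), float(fitness))
            self.trace.append((ffe, float(fitness)))
            return True
        return False


def _evaluate_population(problem, pop: Population, budget: BudgetCounter,
                         tracker: _Tracker) -> None:
    """Evaluate unset members until done or budget exhausted."""
    from .benchmarks import evaluate  # local import avoids a cycle

    for i in range(pop.size):
        if not np.isnan(pop.fitness[i]):
            continue
        if budget.exhausted:
            break
        pop.fitness[i] = evaluate(problem, pop.positions[i], budget)
        tracker.offer(pop.positions[i], pop.fitness[i], budget.used)


def _main_loop(problem, pop: Population, config: OptimizerConfig,
               budget: BudgetCounter, tracker: _Tracker,
               search_rng, cls_rng=None, use_cls: bool = False) -> None:
    from .benchmarks import evaluate
    from .chaos import chaotic_local_search, shrinkage

    bounds = problem.bounds
    while not budget.exhausted:
        improved = False
        for i in range(pop.size):
            if budget.exhausted:
                break
            member = Solution(pop.positions[i], pop.fitness[i])
            candidate = osphresis_step(member, bounds, config.step_scale, search_rng)
            f = evaluate(problem, candidate, budget)
            # Candidates are scouting flights: members keep their location
            # unless the vision phase relocates the whole swarm to a new best.
            improved |= tracker.offer(candidate, f, budget.used)
        vision_update(pop, tracker.best, improved)
        if use_cls and budget.used > config.cls_trigger and not budget.exhausted:
            lam = shrinkage(budget.used, budget.limit)
            new_best = chaotic_local_search(problem, tracker.best, config.cls_steps,
                                            lam, budget, cls_rng, mu=config.chaos_mu)
            if new_best.fitness < tracker.best.fitness:
                tracker.offer(new_best.position, new_best.fitness, budget.used)
                vision_update(pop, tracker.best, True)


def _resolve_seed(config: OptimizerConfig, rng) -> tuple:
    """Return (init_rng, search_rng, cls_rng) from config.seed or an explicit rng."""
    if rng is not None:
        g = as_generator(rng)
        return g, g, g
    seed = 0 if config.seed is None else config.seed
    return substream(seed, "init"), substream(seed, "search"), substream(seed, "cls")


def run_ffo(problem, config: OptimizerConfig, rng=None) -> OptimizationResult:
    """Plain fruit fly optimization under an FFE budget."""
    if config.max_ffes < config.population_size:
        raise InvalidConfiguration("budget smaller than one population evaluation")
    init_rng, search_rng, _ = _resolve_seed(config, rng)
    budget = BudgetCounter(limit=config.max_ffes)
    tracker = _Tracker()
    pop = init_random_population(problem.bounds, config.population_size, init_rng)
    _evaluate_population(problem, pop, budget, tracker)
    vision_update(pop, tracker.best, True)
    _main_loop(problem, pop, config, budget, tracker, search_rng)
    return OptimizationResult(tracker.best.position, tracker.best.fitness,
                              tracker.trace, budget.used)


def run_coffo(problem, config: OptimizerConfig, rng=None) -> OptimizationResult:
    """Chaotic oppositional FFO: chaotic-opposition init (2N FFEs), the FFO
    main loop, and chaotic local search around the best once the spent
    budget exceeds the trigger."""
    from .chaos import chaotic_opposition_init

    if config.max_ffes < 2 * config.population_size:
        raise InvalidConfiguration("budget smaller than the 2N initialization cost")
    if config.population_size % 2 != 0:
        raise InvalidConfiguration("population_size must be even (N/2 splits)")
    init_rng, search_rng, cls_rng = _resolve_seed(config, rng)
    budget = BudgetCounter(limit=config.max_ffes)
    tracker = _Tracker()
    pop = chaotic_opposition_init(problem, config.population_size, init_rng,
                                  budget=budget, mu=config.chaos_mu)
    for i in range(pop.size):
        tracker.offer(pop.positions[i], pop.fitness[i], budget.used)
    vision_update(pop, tracker.best, True)
    _main_loop(problem, pop, config, budget, tracker, search_rng, cls_rng, use_cls=True)
    return OptimizationResult(tracker.best.position, tracker.best.fitness,
                              tracker.trace, budget.used)
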