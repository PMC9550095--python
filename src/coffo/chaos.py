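"""Opposition-based learning, logistic chaotic sequences, the
chaotic-opposition population initialization, and the chaotic local search.

Opposition-based learning (OBL) mirrors a candidate ``x`` inside its box to
``LB + UB - x``; evaluating both and keeping the fitter roughly doubles the
chance of starting near the optimum. The logistic map ``b <- mu*b*(1-b)``
at ``mu = 4`` is chaotic on (0, 1) and supplies deterministic but
well-mixed perturbations; orbits seeded at 0.25, 0.5 or 0.75 collapse, so
those values are excluded when drawing the initial state.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._rng import as_generator
from .core import Bounds, BudgetCounter, Population, Solution, init_random_population
from .errors import InvalidArgument, InvalidConfiguration

__all__ = [
    "opposite_point",
    "logistic_step",
    "draw_chaotic_seed",
    "chaotic_variant",
    "chaotic_opposition_init",
    "shrinkage",
    "chaotic_local_search",
]

# Logistic-map fixed points / pre-fixed points excluded at initialization.
_FORBIDDEN = (0.25, 0.5, 0.75)
_FORBIDDEN_TOL = 1e-12


def opposite_point(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Component-wise opposite ``LB + UB - x`` (an involution)."""
    x = np.asarray(x, dtype=float)
    if not bounds.contains(x):
        raise InvalidArgument("point lies outside the bounds")
    return bounds.lower + bounds.upper - x


def logistic_step(beta, mu: float = 4.0):
    """One logistic-map iterate ``mu * beta * (1 - beta)``; beta in (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0.0) or np.any(beta >= 1.0):
        raise InvalidArgument("beta must lie in the open interval (0, 1)")
    out = mu * beta * (1.0 - beta)
    return float(out) if out.ndim == 0 else out


def draw_chaotic_seed(size: int, rng) -> np.ndarray:
    """Uniform draw in (0, 1) resampled away from {0.25, 0.5, 0.75}."""
    rng = as_generator(rng)
    beta = rng.random(size)
    for _ in range(100):
        bad = (beta <= 0.0) | (beta >= 1.0)
        for v in _FORBIDDEN:
            bad |= np.abs(beta - v) <= _FORBIDDEN_TOL
        if not np.any(bad):
            break
        beta[bad] = rng.random(int(bad.sum()))
    return beta


def chaotic_variant(x: np.ndarray, beta: np.ndarray, bounds: Bounds,
                    mode: str = "literal") -> np.ndarray:
    """Map a solution onto a chaotic sequence.

    ``literal`` multiplies component-wise (``beta * x``, clamped to the
    box); ``normalized`` rescales within the box, ``LB + beta * (x - LB)``,
    which is bound-symmetric but is not the printed form. Default literal.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0.0) or np.any(beta >= 1.0):
        raise InvalidArgument("beta components must lie in (0, 1)")
    if mode == "literal":
        return bounds.clamp(beta * x)
    if mode == "normalized":
        return bounds.lower + beta * (x - bounds.lower)
    raise InvalidArgument(f"unknown chaotic mapping mode {mode!r}")


def chaotic_opposition_init(problem, n: int, rng, budget: Optional[BudgetCounter] = None,
                            mu: float = 4.0, mode: str = "literal") -> Population:
    """Chaotic-opposition initialization.

    Draws N random solutions P, mirrors the first N/2 by OBL, maps the last
    N/2 onto chaotic sequences, evaluates all 2N candidates (2N FFEs), and
    returns the fittest N (stable sort, insertion order breaks ties).
    """
    from .benchmarks import evaluate

    if n < 2 or n % 2 != 0:
        raise InvalidConfiguration("population size must be even and >= 2")
    rng = as_generator(rng)
    bounds = problem.bounds
    base = init_random_population(bounds, n, rng)
    half = n // 2
    opposites = np.array([opposite_point(p, bounds) for p in base.positions[:half]])
    chaotic = np.array([
        chaotic_variant(p, draw_chaotic_seed(bounds.dimension, rng), bounds, mode=mode)
        for p in base.positions[half:]
    ])
    candidates = np.vstack([base.positions, opposites, chaotic])
    if budget is None:
        budget = BudgetCounter(limit=candidates.shape[0])
    fitness = np.array([evaluate(problem, c, budget) for c in candidates])
    order = np.argsort(fitness, kind="stable")[:n]
    return Population(candidates[order].copy(), fitness[order].copy())


def shrinkage(ffe: int, max_ffe: int) -> float:
    """Budget-dependent shrinkage ``(maxFFE - FFE + 1) / maxFFE``.

    Close to 1 early (wide exploration around the best), 1/maxFFE at
    exhaustion (fine-tuned exploitation).
    """
    if max_ffe < 1:
        raise InvalidArgument("max_ffe must be positive")
    if not 1 <= ffe <= max_ffe:
        raise InvalidArgument("ffe must lie in [1, max_ffe]")
    return (max_ffe - ffe + 1) / max_ffe


def chaotic_local_search(problem, best: Solution, k_steps: int, lam: float,
                         budget: BudgetCounter, rng, mu: float = 4.0) -> Solution:
    """Chaotic local search around the global best.

    A fresh chaotic state is drawn per invocation; at each step the state
    advances by the logistic map, is stretched onto the box
    (``S = l + beta * (u - l)``), and blended with the incumbent as
    ``(1 - lam) * x* + lam * S``. Each candidate costs one FFE; the search
    returns on the first strict improvement, or the incumbent unchanged
    after ``k_steps`` failures (or on budget exhaustion mid-search).
    """
    from .benchmarks import evaluate

    if best.fitness is None:
        raise InvalidArgument("best solution must be evaluated")
    if not 0.0 < lam <= 1.0:
        raise InvalidArgument("lambda must lie in (0, 1]")
    rng = as_generator(rng)
    bounds = problem.bounds
    beta = draw_chaotic_seed(bounds.dimension, rng)
    for _ in range(k_steps):
        if budget.exhausted:
            break
        beta = logistic_step(beta, mu)
        # Chaotic orbit can touch {0,1} in floating point; nudge inside.
        beta = np.clip(beta, 1e-16, 1.0 - 1e-16)
        s = bounds.lower + beta * (bounds.upper - bounds.lower)
        candidate = bounds.clamp((1.0 - lam) * best.position + lam * s)
        f = evaluate(problem, candidate, budget)
        if f < best.fitness:
            return Solution(candidate, float(f))
    return best
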