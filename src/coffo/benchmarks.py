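"""Self-contained bound-constrained benchmark objectives.

The registry mirrors the CEC2019 "100-digit challenge" layout: cec01-cec03
are the data-free problems (Storn's Chebyshev polynomial fitting, the
inverse Hilbert matrix, Lennard-Jones minimum energy) at their published
dimensions and ranges; cec04-cec10 are implemented as unshifted, unrotated
analogues of the corresponding classic functions (Rastrigin, Griewank,
Weierstrass, Schwefel, Happy Cat, Ackley, expanded Schaffer F6), each
offset so the global minimum value is 1 - the suite's convention. The
official shift/rotation data files are deliberately not used, so published
per-function scores for cec04-cec10 are not comparable; dimensions, ranges
and the minimum-value convention are.

Every objective is a pure, finite function of its argument; evaluations go
through :func:`evaluate`, which charges exactly one FFE to the budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .core import Bounds, BudgetCounter
from .errors import InvalidArgument

__all__ = ["Problem", "make_benchmark", "make_sphere", "list_problems", "evaluate",
           "PROBLEM_NAMES"]


@dataclass(frozen=True)
class Problem:
    """A named box-constrained objective with known-optimum metadata."""

    name: str
    bounds: Bounds
    objective: Callable[[np.ndarray], float]
    optimum_value: Optional[float] = None
    minimizer: Optional[np.ndarray] = None


def evaluate(problem: Problem, x: np.ndarray, budget: BudgetCounter) -> float:
    """Evaluate the objective at ``x``, charging one FFE."""
    x = np.asarray(x, dtype=float)
    if not problem.bounds.contains(x):
        raise InvalidArgument(f"point outside the bounds of {problem.name}")
    budget.spend()
    return float(problem.objective(x))


# --- cec01: Storn's Chebyshev polynomial fitting, D = 9 -------------------

def _chebyshev(u: np.ndarray) -> float:
    d = u.size
    # T_{d-1}(1.2) by the three-term recurrence.
    a, b = 1.0, 1.2
    for _ in range(d - 2):
        a, b = b, 2.4 * b - a
    target = b
    m = 32 * d
    ys = -1.0 + 2.0 * np.arange(m + 1) / m
    # Horner evaluation of the degree d-1 polynomial at all grid points.
    p = np.full_like(ys, u[0])
    for c in u[1:]:
        p = p * ys + c
    over = np.abs(p) - 1.0
    total = float(np.sum(np.where(over > 0.0, over**2, 0.0)))
    for y in (-1.2, 1.2):
        pv = u[0]
        for c in u[1:]:
            pv = pv * y + c
        if pv < target:
            total += (pv - target) ** 2
    return total


_T8_COEFFS = np.array([128.0, 0.0, -256.0, 0.0, 160.0, 0.0, -32.0, 0.0, 1.0])


# --- cec02: inverse Hilbert matrix, D = 16 --------------------------------

_HILBERT4 = 1.0 / (np.arange(4)[:, None] + np.arange(4)[None, :] + 1.0)
_HILBERT4_INV = np.array([
    [16.0, -120.0, 240.0, -140.0],
    [-120.0, 1200.0, -2700.0, 1680.0],
    [240.0, -2700.0, 6480.0, -4200.0],
    [-140.0, 1680.0, -4200.0, 2800.0],
])


def _inverse_hilbert(z: np.ndarray) -> float:
    w = _HILBERT4 @ z.reshape(4, 4) - np.eye(4)
    return float(np.abs(w).sum())


# --- cec03: Lennard-Jones minimum energy, D = 18 (6 atoms) ----------------

_LJ_OFFSET = 12.7120622568  # -(known 6-atom minimum energy)


def _lennard_jones(x: np.ndarray) -> float:
    pts = x.reshape(-1, 3)
    diff = pts[:, None, :] - pts[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    iu = np.triu_indices(pts.shape[0], k=1)
    r2 = np.maximum(r2[iu], 1e-12)  # guard against coincident atoms
    inv6 = 1.0 / r2**3
    return float(np.sum(inv6 * inv6 - 2.0 * inv6)) + _LJ_OFFSET


# --- cec04..cec10: unshifted classic analogues ----------------------------

def _rastrigin(x: np.ndarray) -> float:
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _griewank(x: np.ndarray) -> float:
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


_W_A, _W_B, _W_KMAX = 0.5, 3.0, 20
_W_AK = _W_A ** np.arange(_W_KMAX + 1)
_W_BK = _W_B ** np.arange(_W_KMAX + 1)
_W_BIAS = float(np.sum(_W_AK * np.cos(np.pi * _W_BK)))


def _weierstrass(x: np.ndarray) -> float:
    inner = np.sum(_W_AK * np.cos(2.0 * np.pi * _W_BK * (x[:, None] + 0.5)), axis=1)
    return float(np.sum(inner) - x.size * _W_BIAS)


_SCHWEFEL_CONST = 418.9828872724338


def _schwefel(x: np.ndarray) -> float:
    z = 10.0 * x  # [-100,100] box mapped onto the classic [-1000,1000] domain
    return float(_SCHWEFEL_CONST * x.size - np.sum(z * np.sin(np.sqrt(np.abs(z)))))


def _happy_cat(x: np.ndarray) -> float:
    d = x.size
    s2 = float(np.sum(x * x))
    s1 = float(np.sum(x))
    return abs(s2 - d) ** 0.25 + (0.5 * s2 + s1) / d + 0.5


def _ackley(x: np.ndarray) -> float:
    d = x.size
    return float(-20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
                 - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d) + 20.0 + np.e)


def _schaffer_f6_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    r2 = x * x + y * y
    return 0.5 + (np.sin(np.sqrt(r2)) ** 2 - 0.5) / (1.0 + 0.001 * r2) ** 2


def _expanded_schaffer(x: np.ndarray) -> float:
    return float(np.sum(_schaffer_f6_pair(x, np.roll(x, -1))))


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _offset(fn: Callable[[np.ndarray], float], c: float) -> Callable[[np.ndarray], float]:
    return lambda x: fn(x) + c


# name -> (objective, dimension, low, high, optimum_value, minimizer)
_REGISTRY = {
    "cec01": (_offset(_chebyshev, 1.0), 9, -8192.0, 8192.0, 1.0, _T8_COEFFS),
    "cec02": (_offset(_inverse_hilbert, 1.0), 16, -16384.0, 16384.0, 1.0,
              _HILBERT4_INV.ravel()),
    "cec03": (_offset(_lennard_jones, 1.0), 18, -4.0, 4.0, 1.0, None),
    "cec04": (_offset(_rastrigin, 1.0), 10, -100.0, 100.0, 1.0, np.zeros(10)),
    "cec05": (_offset(_griewank, 1.0), 10, -100.0, 100.0, 1.0, np.zeros(10)),
    "cec06": (_offset(_weierstrass, 1.0), 10, -100.0, 100.0, 1.0, np.zeros(10)),
    "cec07": (_offset(_schwefel, 1.0), 10, -100.0, 100.0, 1.0, None),
    "cec08": (_offset(_happy_cat, 1.0), 10, -100.0, 100.0, 1.0, -np.ones(10)),
    "cec09": (_offset(_ackley, 1.0), 10, -100.0, 100.0, 1.0, np.zeros(10)),
    "cec10": (_offset(_expanded_schaffer, 1.0), 10, -100.0, 100.0, 1.0, np.zeros(10)),
    "sphere": (_sphere, 10, -100.0, 100.0, 0.0, np.zeros(10)),
    "rastrigin-raw": (_rastrigin, 10, -5.12, 5.12, 0.0, np.zeros(10)),
}

PROBLEM_NAMES = tuple(_REGISTRY)


def make_benchmark(name: str) -> Problem:
    """Instantiate a registered benchmark problem by name."""
    if name not in _REGISTRY:
        raise InvalidArgument(f"unknown problem {name!r}; known: {', '.join(_REGISTRY)}")
    fn, dim, low, high, opt, minimizer = _REGISTRY[name]
    return Problem(name=name, bounds=Bounds.box(low, high, dim), objective=fn,
                   optimum_value=opt,
                   minimizer=None if minimizer is None else minimizer.copy())


def make_sphere(dimension: int, low: float = -100.0, high: float = 100.0) -> Problem:
    """A sphere problem at an arbitrary dimension and range."""
    return Problem(name=f"sphere-{dimension}d", bounds=Bounds.box(low, high, dimension),
                   objective=_sphere, optimum_value=0.0, minimizer=np.zeros(dimension))


def list_problems() -> list:
    """Registry summary: (name, dimension, low, high, optimum_value)."""
    return [(name, dim, low, high, opt)
            for name, (fn, dim, low, high, opt, mz) in _REGISTRY.items()]
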