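"""Wrapper feature selection with binary FFO/COFFO.

Each swarm member carries a bit mask (1 = feature selected) paired with a
continuous *companion* position confined to a fixed box. The continuous
machinery (osphresis walk, chaotic-opposition init, chaotic local search)
acts on the companions; a V-shaped transfer function maps a displacement
magnitude to a flip probability, and bits are complemented with that
probability. The fitness of a mask blends the stratified-CV error of a
KNN classifier restricted to the selected columns with the fraction of
features retained:

    fit = alpha * ER + (1 - alpha) * |S| / |O|

so accuracy dominates (alpha = 0.99 by default) and the subset-size term
breaks ties toward smaller masks.

Binarization. V-shaped transfer functions measure how far a member moved,
so the flip argument used by the search driver is the companion
displacement of the current move, scaled by the budget shrinkage
lambda = (maxFFE - FFE + 1)/maxFFE raised to a fixed exponent: early
candidates differ from their parents in many bits (exploration), late
candidates in one or two (exploitation). At least one bit always flips -
a zero-flip candidate would duplicate its parent and waste an FFE. The
plain rule with the companion position itself as the argument is what
:func:`binarize_step` computes when no explicit argument is passed.

The cross-validation partition is drawn once per run and reused by every
fitness evaluation, which keeps the fitness deterministic within a run
and makes the mask -> error cache valid. Every candidate evaluation costs
one FFE whether or not its error was cached; the budget, not the cache,
terminates a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from ._rng import as_generator, substream
from .core import Bounds, BudgetCounter, Solution, osphresis_step
from .chaos import (chaotic_variant, draw_chaotic_seed, logistic_step,
                    opposite_point, shrinkage)
from .errors import InvalidArgument, InvalidConfiguration, InvalidDataset

__all__ = [
    "Dataset",
    "BinaryState",
    "FitnessWeights",
    "FSConfig",
    "FSResult",
    "transfer_v",
    "binarize_step",
    "initial_bits",
    "knn_error",
    "fs_fitness",
    "selection_ratio",
    "run_fs",
]


@dataclass
class Dataset:
    """A numeric classification table: rows = samples, labels encoded as
    integers. Loaders are responsible for imputation and label encoding;
    a dataset object never contains missing values."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: Optional[list] = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise InvalidDataset("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise InvalidDataset("labels must align with feature rows")
        if np.isnan(self.features).any():
            raise InvalidDataset("dataset contains missing values; impute at load time")
        if np.unique(self.labels).size < 2:
            raise InvalidDataset("dataset must contain at least 2 classes")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class BinaryState:
    """A feature mask plus the continuous companion that drives flips."""

    bits: np.ndarray  # bool (n_features,)
    companion: np.ndarray  # float (n_features,)

    def copy(self) -> "BinaryState":
        return BinaryState(self.bits.copy(), self.companion.copy())


@dataclass(frozen=True)
class FitnessWeights:
    """alpha weighs the classification error; 1 - alpha the subset size."""

    alpha: float = 0.99

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidArgument("alpha must lie in [0, 1]")

    @property
    def beta_w(self) -> float:
        return 1.0 - self.alpha


_SQRT_PI_HALF = np.sqrt(np.pi) / 2.0

_TRANSFERS = {
    "V1": lambda x: np.abs(erf(_SQRT_PI_HALF * x)),
    "V2": lambda x: np.abs(np.tanh(x)),
    "V3": lambda x: np.abs(x / np.sqrt(1.0 + x * x)),
    "V4": lambda x: np.abs((2.0 / np.pi) * np.arctan((np.pi / 2.0) * x)),
}


def transfer_v(name: str, x):
    """V-shaped transfer function value(s) in [0, 1)."""
    if name not in _TRANSFERS:
        raise InvalidArgument(f"unknown transfer function {name!r}; known: V1..V4")
    x = np.asarray(x, dtype=float)
    out = _TRANSFERS[name](x)
    return float(out) if out.ndim == 0 else out


def _repair_empty(bits: np.ndarray, rng) -> np.ndarray:
    if not bits.any():
        bits[rng.integers(bits.size)] = True
    return bits


def binarize_step(state: BinaryState, tf_name: str, rng, argument=None,
                  min_flips: int = 0) -> BinaryState:
    """Flip each bit with probability T(argument_j), then repair an empty
    mask by setting one uniformly random bit.

    ``argument`` defaults to the companion position (the plain rule); the
    search driver passes the shrinkage-scaled displacement of the current
    move instead. With ``min_flips=1`` a candidate that drew no flips gets
    one uniformly random bit complemented.
    """
    rng = as_generator(rng)
    arg = state.companion if argument is None else np.asarray(argument, dtype=float)
    prob = transfer_v(tf_name, arg)
    flips = rng.random(state.bits.size) < prob
    if min_flips > 0 and not flips.any():
        flips[rng.integers(flips.size)] = True
    bits = np.where(flips, ~state.bits, state.bits)
    return BinaryState(_repair_empty(bits, rng), state.companion.copy())


def initial_bits(companion: np.ndarray, tf_name: str, rng) -> np.ndarray:
    """One-shot binarization of a companion: bit j set with probability
    T(companion_j) (the plain flip rule applied to an all-zero mask), then
    empty-mask repair."""
    rng = as_generator(rng)
    bits = rng.random(companion.size) < transfer_v(tf_name, companion)
    return _repair_empty(bits, rng)


def knn_error(data: Dataset, mask: np.ndarray, k: int = 5, n_folds: int = 10,
              fold_seed: int = 0) -> float:
    """Stratified n-fold CV error of KNN (Euclidean) on the masked columns."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidArgument("mask must select at least one feature")
    _check_class_sizes(data.labels, n_folds)
    x = data.features[:, mask]
    y = data.labels
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    wrong = 0
    for train_idx, test_idx in splitter.split(x, y):
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(x[train_idx], y[train_idx])
        wrong += int(np.sum(clf.predict(x[test_idx]) != y[test_idx]))
    return wrong / data.n_samples


def _check_class_sizes(labels: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise InvalidDataset(f"every class needs >= {n_folds} members for "
                             f"{n_folds}-fold stratified CV")


# Above this many floats the per-feature distance tensor is not materialized.
_FAST_CV_MAX_FLOATS = 200_000_000


class _FastCV:
    """Precomputed-distance CV evaluator, numerically identical to the
    sklearn path in :func:`knn_error` (same folds, same neighbor rule).

    The masked squared Euclidean distance matrix is one matrix-vector
    product over a precomputed (n*n, p) per-feature squared-difference
    table, so each mask evaluation avoids refitting a classifier per fold.
    """

    def __init__(self, data: Dataset, k: int, n_folds: int, fold_seed: int):
        _check_class_sizes(data.labels, n_folds)
        self.k = k
        self.n = data.n_samples
        x = data.features
        diffs = x[:, None, :] - x[None, :, :]
        self._d2 = (diffs * diffs).reshape(self.n * self.n, data.n_features)
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=fold_seed)
        self._folds = list(splitter.split(x, data.labels))
        classes, self._ymap = np.unique(data.labels, return_inverse=True)
        self._n_classes = classes.size

    def error(self, mask: np.ndarray) -> float:
        dist = (self._d2 @ np.asarray(mask, dtype=float)).reshape(self.n, self.n)
        wrong = 0
        for train_idx, test_idx in self._folds:
            sub = dist[np.ix_(test_idx, train_idx)]
            k = min(self.k, train_idx.size)
            nearest = np.argpartition(sub, k - 1, axis=1)[:, :k]
            votes = self._ymap[train_idx][nearest]
            for row, true in zip(votes, self._ymap[test_idx]):
                if np.bincount(row, minlength=self._n_classes).argmax() != true:
                    wrong += 1
        return wrong / self.n


def fs_fitness(er: float, subset_size: int, total: int,
               weights: FitnessWeights = FitnessWeights()) -> float:
    """Blended objective alpha*ER + (1-alpha)*|S|/|O|."""
    if not 0.0 <= er <= 1.0:
        raise InvalidArgument("error rate must lie in [0, 1]")
    if not 1 <= subset_size <= total:
        raise InvalidArgument("subset size must lie in [1, total]")
    return weights.alpha * er + weights.beta_w * subset_size / total


def selection_ratio(mask: np.ndarray) -> float:
    """Fraction of features retained, |S| / |O|."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        raise InvalidArgument("mask must be non-empty")
    return float(mask.sum()) / mask.size


def _minmax_scale(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0.0] = 1.0  # constant columns map to 0
    return (x - lo) / span


@dataclass(frozen=True)
class FSConfig:
    """Feature-selection experiment configuration.

    Defaults follow the comparison protocol: N = 10 members, budget
    maxFFEs = N + N*maxIter = 1,010 evaluations, 20 independent runs, KNN
    with k = 5 under stratified 10-fold CV, alpha = 0.99, V2 (tanh)
    transfer function, companions confined to [-4, 4]. ``flip_anneal`` is
    the exponent on the budget shrinkage in the flip-probability argument.
    """

    algo: str = "coffo"
    population_size: int = 10
    max_ffes: int = 1_010
    runs: int = 20
    knn_k: int = 5
    n_folds: int = 10
    alpha: float = 0.99
    transfer: str = "V2"
    companion_low: float = -4.0
    companion_high: float = 4.0
    cls_steps: int = 4
    cls_trigger: Optional[int] = None  # None -> max_ffes // 3
    chaos_mu: float = 4.0
    step_scale: float = 1.0
    flip_anneal: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.algo not in ("ffo", "coffo"):
            raise InvalidConfiguration("algo must be 'ffo' or 'coffo'")
        if self.transfer not in _TRANSFERS:
            raise InvalidConfiguration("transfer must be one of V1..V4")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidConfiguration("alpha must lie in [0, 1]")
        if self.companion_low >= self.companion_high:
            raise InvalidConfiguration("companion box must be non-degenerate")
        if self.runs < 1 or self.population_size < 1 or self.max_ffes < 1:
            raise InvalidConfiguration("runs, population size and budget must be positive")
        if self.flip_anneal < 0:
            raise InvalidConfiguration("flip_anneal must be non-negative")
        trigger = self.max_ffes // 3 if self.cls_trigger is None else self.cls_trigger
        if not 0 <= trigger <= self.max_ffes:
            raise InvalidConfiguration("cls_trigger must lie in [0, max_ffes]")
        object.__setattr__(self, "cls_trigger", int(trigger))


@dataclass
class FSResult:
    """Summary of R independent feature-selection runs."""

    per_run_fitness: np.ndarray  # best fitness of each run
    per_run_masks: np.ndarray  # (runs, n_features) bool
    best_fitness: float
    mean_fitness: float
    std_fitness: float
    best_mask: np.ndarray
    accuracy: float
    selection_ratio: float
    selection_frequency: np.ndarray  # per-feature frequency over run-best masks
    traces: list = field(default_factory=list)  # per-run best-so-far traces


class _MaskFitness:
    """Mask -> fitness with a per-run error cache; charges 1 FFE per call."""

    def __init__(self, data: Dataset, config: FSConfig, fold_seed: int,
                 budget: BudgetCounter):
        self.data = data
        self.config = config
        self.fold_seed = fold_seed
        self.budget = budget
        self.weights = FitnessWeights(config.alpha)
        self._er_cache: dict = {}
        self._fast = None
        if data.n_samples**2 * data.n_features <= _FAST_CV_MAX_FLOATS:
            self._fast = _FastCV(data, config.knn_k, config.n_folds, fold_seed)

    def error(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in self._er_cache:
            if self._fast is not None:
                er = self._fast.error(mask)
            else:
                er = knn_error(self.data, mask, k=self.config.knn_k,
                               n_folds=self.config.n_folds,
                               fold_seed=self.fold_seed)
            self._er_cache[key] = er
        return self._er_cache[key]

    def __call__(self, mask: np.ndarray) -> float:
        self.budget.spend()
        return fs_fitness(self.error(mask), int(mask.sum()), mask.size, self.weights)


class _BinaryTracker:
    def __init__(self):
        self.best: Optional[BinaryState] = None
        self.best_fitness = np.inf
        self.trace: list = []
        self.final_error: float = np.nan

    def offer(self, state: BinaryState, fitness: float, ffe: int) -> bool:
        if fitness < self.best_fitness:
            self.best = state.copy()
            self.best_fitness = float(fitness)
            self.trace.append((ffe, float(fitness)))
            return True
        return False


def _flip_argument(displacement: np.ndarray, budget: BudgetCounter,
                   config: FSConfig) -> np.ndarray:
    lam = shrinkage(max(budget.used, 1), budget.limit) ** config.flip_anneal
    return lam * displacement


def _binary_init(fitness: _MaskFitness, config: FSConfig, box: Bounds, rng,
                 tracker: _BinaryTracker) -> list:
    """Population init: plain random companions for FFO (N FFEs); the
    chaotic-opposition scheme applied to companions for COFFO (2N FFEs).
    Bit masks start uniform Bernoulli(1/2)."""
    n = config.population_size
    span = box.upper - box.lower
    companions = box.lower + rng.random((n, box.dimension)) * span
    if config.algo == "coffo":
        if n % 2 != 0:
            raise InvalidConfiguration("COFFO needs an even population size")
        half = n // 2
        opp = np.array([opposite_point(c, box) for c in companions[:half]])
        cha = np.array([chaotic_variant(c, draw_chaotic_seed(box.dimension, rng), box)
                        for c in companions[half:]])
        companions = np.vstack([companions, opp, cha])
    states, values = [], []
    for comp in companions:
        if fitness.budget.exhausted:
            break
        bits = _repair_empty(rng.random(box.dimension) < 0.5, rng)
        state = BinaryState(bits, comp.copy())
        f = fitness(state.bits)
        tracker.offer(state, f, fitness.budget.used)
        states.append(state)
        values.append(f)
    order = np.argsort(values, kind="stable")[:n]
    return [(states[i], values[i]) for i in order]


def _binary_cls(fitness: _MaskFitness, config: FSConfig, box: Bounds,
                tracker: _BinaryTracker, rng) -> None:
    """Chaotic local search on the best member's companion."""
    lam = shrinkage(fitness.budget.used, fitness.budget.limit)
    beta = draw_chaotic_seed(box.dimension, rng)
    for _ in range(config.cls_steps):
        if fitness.budget.exhausted:
            return
        beta = np.clip(logistic_step(beta, config.chaos_mu), 1e-16, 1.0 - 1e-16)
        s = box.lower + beta * (box.upper - box.lower)
        comp = box.clamp((1.0 - lam) * tracker.best.companion + lam * s)
        arg = _flip_argument(comp - tracker.best.companion, fitness.budget, config)
        cand = binarize_step(BinaryState(tracker.best.bits.copy(), comp),
                             config.transfer, rng, argument=arg, min_flips=1)
        f = fitness(cand.bits)
        if tracker.offer(cand, f, fitness.budget.used):
            return


def _run_binary_once(data: Dataset, config: FSConfig, run_seed: int) -> _BinaryTracker:
    budget = BudgetCounter(limit=config.max_ffes)
    fold_rng = substream(run_seed, "folds")
    fitness = _MaskFitness(data, config, int(fold_rng.integers(2**31)), budget)
    rng = substream(run_seed, "binary")
    box = Bounds.box(config.companion_low, config.companion_high, data.n_features)
    tracker = _BinaryTracker()
    members = _binary_init(fitness, config, box, rng, tracker)
    while not budget.exhausted:
        improved = False
        for i, (state, value) in enumerate(members):
            if budget.exhausted:
                break
            comp = osphresis_step(Solution(state.companion), box, config.step_scale, rng)
            arg = _flip_argument(comp - state.companion, budget, config)
            cand = binarize_step(BinaryState(state.bits.copy(), comp),
                                 config.transfer, rng, argument=arg, min_flips=1)
            f = fitness(cand.bits)
            # Candidates are scouting flights; members move only when the
            # vision phase relocates the swarm to a new best.
            improved |= tracker.offer(cand, f, budget.used)
        if improved:  # vision phase: the swarm relocates to the best
            members = [(tracker.best.copy(), tracker.best_fitness) for _ in members]
        if (config.algo == "coffo" and budget.used > config.cls_trigger
                and not budget.exhausted):
            before = tracker.best_fitness
            _binary_cls(fitness, config, box, tracker, rng)
            if tracker.best_fitness < before:
                members = [(tracker.best.copy(), tracker.best_fitness)
                           for _ in members]
    tracker.final_error = fitness.error(tracker.best.bits)
    return tracker


def run_fs(data: Dataset, config: FSConfig = FSConfig(), seed: Optional[int] = None) -> FSResult:
    """Run R independent binary FFO/COFFO feature-selection searches.

    Features are min-max scaled per column before KNN (Euclidean distance
    is scale-sensitive). The reported accuracy is 1 - ER of the best run's
    mask under the same CV protocol that drove the search.
    """
    root_seed = config.seed if seed is None else seed
    scaled = Dataset(_minmax_scale(data.features), data.labels, data.feature_names)
    run_seed_rng = substream(root_seed, "runs")
    run_seeds = run_seed_rng.integers(2**31, size=config.runs)
    fitnesses, masks, traces, errors = [], [], [], []
    for r in range(config.runs):
        tracker = _run_binary_once(scaled, config, int(run_seeds[r]))
        fitnesses.append(tracker.best_fitness)
        masks.append(tracker.best.bits.copy())
        errors.append(tracker.final_error)
        traces.append(tracker.trace)
    fitnesses = np.asarray(fitnesses)
    masks = np.asarray(masks)
    best_run = int(np.argmin(fitnesses))
    best_mask = masks[best_run]
    return FSResult(
        per_run_fitness=fitnesses,
        per_run_masks=masks,
        best_fitness=float(fitnesses[best_run]),
        mean_fitness=float(fitnesses.mean()),
        std_fitness=float(fitnesses.std(ddof=0)),
        best_mask=best_mask,
        accuracy=1.0 - errors[best_run],
        selection_ratio=selection_ratio(best_mask),
        selection_frequency=masks.mean(axis=0),
        traces=traces,
    )
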