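"""Synthetic two-class tabular datasets with a planted informative subset.

The wrapper feature-selection layer needs data whose ground truth is known:
a handful of columns carry a class-mean shift (a Gaussian signal of
controllable effect size, in units of the unit noise SD) while the rest
are label-independent standard-normal noise. Columns are randomly permuted
and the planted indices reported post-permutation, so recovery can be
scored (e.g. by the Jaccard index between a selected mask and the planted
set).

A second generator emulates the 15-column layout of a COVID-19 patient
outcome table (id, location, country, gender, age, dates, travel flags,
six clinical symptoms) with a binary death/recovery label. By default only
gender, age and symptom_2 carry signal; id and symptom_6 are
label-independent by construction, so a sound wrapper should never pay the
subset-size penalty to keep them. Categorical fields are encoded as small
integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._rng import as_generator
from .errors import InvalidArgument
from .feature_selection import Dataset

__all__ = ["GeneratorSpec", "generate_classification", "generate_covidlike",
           "COVID_FEATURE_NAMES"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the planted-subset generator.

    effect_size is the class-mean separation in noise-SD units: informative
    columns are N(-effect_size/2, 1) in class 0 and N(+effect_size/2, 1) in
    class 1.
    """

    n_samples: int = 200
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 2.0
    class_balance: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self):
        if not 1 <= self.n_informative <= self.n_features:
            raise InvalidArgument("need 1 <= n_informative <= n_features")
        if self.effect_size < 0:
            raise InvalidArgument("effect_size must be non-negative")
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidArgument("class_balance must lie in (0, 1)")


def generate_classification(spec: GeneratorSpec, rng=None) -> tuple[Dataset, np.ndarray]:
    """Generate a dataset per ``spec``; returns (dataset, planted indices).

    The planted indices refer to columns after the random permutation and
    are sorted ascending.
    """
    rng = as_generator(spec.seed if rng is None else rng)
    n, p, s = spec.n_samples, spec.n_features, spec.n_informative
    labels = (rng.random(n) < spec.class_balance).astype(int)
    x = rng.standard_normal((n, p))
    shift = np.where(labels == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    x[:, :s] += shift[:, None]
    perm = rng.permutation(p)
    x = x[:, perm]
    planted = np.sort(np.argsort(perm)[:s])
    names = [f"f{j}" for j in range(p)]
    return Dataset(features=x, labels=labels, feature_names=names), planted


COVID_FEATURE_NAMES = (
    "id", "location", "country", "gender", "age", "sym_on", "hosp_vis",
    "vis_wuhan", "from_wuhan", "symptom_1", "symptom_2", "symptom_3",
    "symptom_4", "symptom_5", "symptom_6",
)

_DEFAULT_SIGNAL = ("gender", "age", "symptom_2")


def generate_covidlike(seed: Optional[int] = None, n_samples: int = 400,
                       signal_features: Sequence[str] = _DEFAULT_SIGNAL,
                       death_rate: float = 0.35) -> Dataset:
    """Synthetic 15-feature patient table with a binary death(1)/recovery(0)
    label. Only ``signal_features`` depend on the label; every other column
    (including id and symptom_6) is label-independent."""
    unknown = set(signal_features) - set(COVID_FEATURE_NAMES)
    if unknown:
        raise InvalidArgument(f"unknown signal features: {sorted(unknown)}")
    rng = as_generator(seed)
    n = n_samples
    y = (rng.random(n) < death_rate).astype(int)

    cols = {}
    cols["id"] = np.arange(1, n + 1, dtype=float)
    cols["location"] = rng.integers(0, 12, n).astype(float)
    cols["country"] = rng.integers(0, 6, n).astype(float)
    cols["gender"] = rng.integers(0, 2, n).astype(float)
    cols["age"] = np.clip(rng.normal(45.0, 16.0, n), 0.0, 95.0)
    cols["sym_on"] = rng.integers(0, 31, n).astype(float)
    cols["hosp_vis"] = cols["sym_on"] + rng.integers(0, 10, n)
    cols["vis_wuhan"] = rng.integers(0, 2, n).astype(float)
    cols["from_wuhan"] = rng.integers(0, 2, n).astype(float)
    for j in range(1, 7):
        cols[f"symptom_{j}"] = rng.integers(0, 2, n).astype(float)

    # Overwrite the signal-carrying columns with label-dependent draws.
    if "gender" in signal_features:
        cols["gender"] = (rng.random(n) < np.where(y == 1, 0.72, 0.45)).astype(float)
    if "age" in signal_features:
        cols["age"] = np.clip(np.where(y == 1, rng.normal(66.0, 10.0, n),
                                       rng.normal(42.0, 12.0, n)), 0.0, 95.0)
    for name in signal_features:
        if name.startswith("symptom_"):
            cols[name] = (rng.random(n) < np.where(y == 1, 0.75, 0.20)).astype(float)
    if "id" in signal_features or "symptom_6" in signal_features:
        raise InvalidArgument("id and symptom_6 are zero-signal by contract")

    x = np.column_stack([cols[name] for name in COVID_FEATURE_NAMES])
    return Dataset(features=x, labels=y, feature_names=list(COVID_FEATURE_NAMES))
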