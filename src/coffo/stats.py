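"""Nonparametric comparison of optimizers across a problem suite.

Given an n-problems x k-methods score table (lower is better by default),
the pipeline is: per-problem Friedman ranks with average ranks on ties,
the Friedman chi-square statistic, the Iman-Davenport F refinement, and -
once the omnibus null is rejected - Holm's step-down procedure comparing a
control method against the rest. A Wilcoxon signed-rank test with exact
enumeration of the sign-assignment null (ties get average ranks, zero
differences are dropped) covers paired per-dataset comparisons.

The two published comparison tables for 12 optimizers on the CEC2019 suite
that the examples and tests use as printed inputs are bundled and exposed
via :func:`load_reference_scores` / :func:`load_reference_ranks`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgument

__all__ = [
    "RankTable",
    "friedman_ranks",
    "friedman_statistic",
    "iman_davenport",
    "critical_values",
    "holm_stepdown",
    "wilcoxon_signed_rank",
    "compare_methods",
    "load_reference_scores",
    "load_reference_ranks",
]


@dataclass
class RankTable:
    """Per-problem ranks (rows) and the column average ranks."""

    ranks: pd.DataFrame
    average_ranks: pd.Series

    @property
    def n_problems(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_methods(self) -> int:
        return self.ranks.shape[1]

    @classmethod
    def from_ranks(cls, ranks: pd.DataFrame) -> "RankTable":
        return cls(ranks, ranks.mean(axis=0))


def _check_scores(scores: pd.DataFrame) -> None:
    if scores.isna().any().any() or not np.isfinite(scores.to_numpy()).all():
        raise InvalidArgument("score table must be finite with no missing cells")
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise InvalidArgument("need at least 2 problems and 2 methods")


def friedman_ranks(scores: pd.DataFrame, higher_is_better: bool = False) -> RankTable:
    """Rank methods within every problem row; ties share average ranks."""
    _check_scores(scores)
    values = scores.to_numpy(dtype=float)
    if higher_is_better:
        values = -values
    ranks = np.apply_along_axis(sps.rankdata, 1, values)  # 'average' method
    rank_df = pd.DataFrame(ranks, index=scores.index, columns=scores.columns)
    return RankTable.from_ranks(rank_df)


def friedman_statistic(ranks: RankTable, n: int | None = None,
                       k: int | None = None) -> float:
    """Friedman chi-square: 12n/(k(k+1)) * sum(Rbar_j^2) - 3n(k+1)."""
    n = ranks.n_problems if n is None else n
    k = ranks.n_methods if k is None else k
    if (n, k) != (ranks.n_problems, ranks.n_methods):
        raise InvalidArgument("n, k do not match the rank table shape")
    rbar = ranks.average_ranks.to_numpy(dtype=float)
    return float(12.0 * n / (k * (k + 1)) * np.sum(rbar**2) - 3.0 * n * (k + 1))


def iman_davenport(chi2: float, n: int, k: int) -> float:
    """Iman-Davenport F refinement: (n-1) chi2 / (n(k-1) - chi2)."""
    if chi2 >= n * (k - 1):
        raise InvalidArgument("degenerate statistic: chi2 must be below n(k-1)")
    return float((n - 1) * chi2 / (n * (k - 1) - chi2))


def critical_values(alpha: float, n: int, k: int) -> tuple[float, float]:
    """Upper-alpha quantiles: chi-square with k-1 df, and F with
    (k-1, (k-1)(n-1)) df."""
    if not 0.0 < alpha < 1.0:
        raise InvalidArgument("alpha must lie in (0, 1)")
    chi2_crit = float(sps.chi2.ppf(1.0 - alpha, df=k - 1))
    f_crit = float(sps.f.ppf(1.0 - alpha, dfn=k - 1, dfd=(k - 1) * (n - 1)))
    return chi2_crit, f_crit


def holm_stepdown(average_ranks: pd.Series, control: str, n: int,
                  alphas: Sequence[float] = (0.05, 0.1),
                  sided: str = "one") -> pd.DataFrame:
    """Holm's step-down procedure against a control method.

    z_j = (Rbar_j - Rbar_control) / sqrt(k(k+1)/(6n)); p from the standard
    normal upper tail (one-sided: the control is hypothesized better; the
    two-sided variant doubles the tail). p-values sort ascending; the
    threshold at sort index i is alpha/(m - i) with m = k - 1 comparisons;
    rejection proceeds while p < threshold and stops at the first failure.
    """
    if control not in average_ranks.index:
        raise InvalidArgument(f"control method {control!r} not in the rank table")
    if sided not in ("one", "two"):
        raise InvalidArgument("sided must be 'one' or 'two'")
    k = average_ranks.size
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    others = average_ranks.drop(control)
    z = (others - average_ranks[control]) / se
    p = pd.Series(sps.norm.sf(z.to_numpy()), index=others.index)
    if sided == "two":
        p = (2.0 * np.minimum(p, 1.0 - p)).clip(upper=1.0)
    order = p.sort_values(kind="stable").index
    m = k - 1
    rows = []
    rejecting = {a: True for a in alphas}
    for i, method in enumerate(order):
        row = {"comparison": f"{control} vs {method}", "method": method,
               "z": float(z[method]), "p_value": float(p[method]), "rank": i}
        for a in alphas:
            threshold = a / (m - i)
            rejecting[a] = rejecting[a] and (row["p_value"] < threshold)
            row[f"threshold_{a}"] = threshold
            row[f"reject_{a}"] = bool(rejecting[a])
        rows.append(row)
    return pd.DataFrame(rows)


def _exact_sf_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled positive-rank sum (DP)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        counts[r:] = counts[r:] + counts[:-r or None]
    return counts


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float],
                         sided: str = "two", alternative: str = "less",
                         exact_limit: int = 25) -> float:
    """Wilcoxon signed-rank test for paired scores.

    Zero differences are dropped; tied absolute differences receive average
    ranks. For n <= ``exact_limit`` the p-value enumerates the 2^n
    equiprobable sign assignments exactly (via dynamic programming over the
    doubled, hence integer, rank sums); above that a normal approximation
    with tie correction and continuity correction is used.

    ``alternative='less'`` tests whether ``a`` is stochastically smaller
    than ``b`` (lower scores = better method); ``sided='two'`` doubles the
    smaller tail.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgument("a and b must be 1-D vectors of equal length")
    if sided not in ("one", "two"):
        raise InvalidArgument("sided must be 'one' or 'two'")
    if alternative not in ("less", "greater"):
        raise InvalidArgument("alternative must be 'less' or 'greater'")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise InvalidArgument("all differences are zero; the test is undefined")
    if n < 5:
        pass  # exact enumeration is still valid, just low-powered
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    total = float(ranks.sum())  # n(n+1)/2

    if n <= exact_limit:
        doubled = np.rint(2.0 * ranks).astype(int)
        counts = _exact_sf_counts(doubled)
        denom = counts.sum()  # 2^n
        w2 = int(round(2.0 * w_plus))
        p_upper = counts[w2:].sum() / denom  # P(W+ >= w)
        p_lower = counts[: w2 + 1].sum() / denom  # P(W+ <= w)
    else:
        mean = total / 2.0
        ties = pd.Series(np.abs(d)).value_counts().to_numpy()
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(ties**3 - ties) / 48.0
        sd = np.sqrt(var)
        p_upper = float(sps.norm.sf((w_plus - 0.5 - mean) / sd))
        p_lower = float(sps.norm.cdf((w_plus + 0.5 - mean) / sd))

    # 'less' = a below b = negative differences dominate = small W+.
    p_one = p_lower if alternative == "less" else p_upper
    if sided == "one":
        return float(min(p_one, 1.0))
    return float(min(2.0 * min(p_lower, p_upper), 1.0))


def compare_methods(scores: pd.DataFrame, control: str, alpha: float = 0.05,
                    higher_is_better: bool = False,
                    alphas: Sequence[float] = (0.05, 0.1)) -> dict:
    """Run the full pipeline on a score table; returns a result dict with
    the rank table, omnibus statistics with critical values and p-values,
    and the Holm table against ``control``."""
    rank_table = friedman_ranks(scores, higher_is_better=higher_is_better)
    n, k = rank_table.n_problems, rank_table.n_methods
    chi2 = friedman_statistic(rank_table)
    f_id = iman_davenport(chi2, n, k)
    chi2_crit, f_crit = critical_values(alpha, n, k)
    holm = holm_stepdown(rank_table.average_ranks, control, n, alphas=alphas)
    return {
        "rank_table": rank_table,
        "friedman_chi2": chi2,
        "friedman_p": float(sps.chi2.sf(chi2, df=k - 1)),
        "chi2_critical": chi2_crit,
        "iman_davenport": f_id,
        "iman_davenport_p": float(sps.f.sf(f_id, dfn=k - 1, dfd=(k - 1) * (n - 1))),
        "f_critical": f_crit,
        "holm": holm,
        "n": n,
        "k": k,
        "alpha": alpha,
    }


def _load_bundled(name: str) -> pd.DataFrame:
    with resources.files("coffo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, index_col="problem")


def load_reference_scores() -> pd.DataFrame:
    """Published mean-fitness table (10 CEC2019 problems x 12 optimizers)."""
    return _load_bundled("cec2019_mean_fitness.csv")


def load_reference_ranks() -> RankTable:
    """Published Friedman rank table for the same comparison."""
    return RankTable.from_ranks(_load_bundled("cec2019_friedman_ranks.csv"))
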