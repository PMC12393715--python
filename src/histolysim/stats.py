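"""Rank-based two-sample tests for arrangement comparisons.

Brunner-Munzel compares the rank averages of two samples (a
location-shift-free alternative to Wilcoxon that tolerates unequal
variances); Siegel-Tukey compares their dispersions by assigning
alternating extreme ranks to the pooled sorted sample and running a
rank-sum test on those ranks.  Both are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "brunner_munzel", "siegel_tukey",
           "siegel_tukey_ranks", "relative_effect"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int
    #: estimated P(X < Y) + 0.5 P(X = Y) (Brunner-Munzel only)
    p_hat: float | None = None


def relative_effect(x, y) -> float:
    """The stochastic-superiority estimate p-hat = P(X < Y) + 0.5 P(X = Y),
    computed from midranks of the pooled sample."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    ry = ranks[len(x):].mean()
    return float((ry - (len(y) + 1) / 2) / len(x))


def brunner_munzel(x, y, method: str = "t",
                   n_permutations: int = 10_000,
                   rng=None) -> TestResult:
    """Two-sided Brunner-Munzel test with midrank ties.

    ``method="t"`` uses the t-distribution approximation with Satterthwaite
    degrees of freedom.  With degenerate rank variance (e.g. completely
    separated samples) that approximation is undefined and a ``ValueError``
    points to ``method="permutation"``, which estimates the p-value by
    randomly permuting group labels and recomputing the statistic's
    studentized numerator (difference of the relative effect from 1/2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least two values")
    p_hat = relative_effect(x, y)
    if method == "t":
        if _bm_degenerate(x, y):
            raise ValueError(
                "degenerate rank variance (e.g. fully separated samples); "
                "use method='permutation' for an exact-style p-value")
        res = sps.brunnermunzel(x, y, alternative="two-sided",
                                distribution="t")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "brunner_munzel", nx, ny, p_hat)
    if method == "permutation":
        rng = rng if rng is not None else np.random.default_rng()
        pooled = np.concatenate([x, y])
        obs = abs(p_hat - 0.5)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            hits += abs(relative_effect(perm[:nx], perm[nx:]) - 0.5) >= \
                obs - 1e-12
        p = (hits + 1) / (n_permutations + 1)
        return TestResult(float(p_hat - 0.5), float(min(p, 1.0)),
                          "brunner_munzel", nx, ny, p_hat)
    raise ValueError(f"unknown method {method!r}")


def _bm_degenerate(x, y) -> bool:
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rix = sps.rankdata(x)
    riy = sps.rankdata(y)
    sx = np.var(rx - rix, ddof=1)
    sy = np.var(ry - riy, ddof=1)
    return sx == 0.0 or sy == 0.0


def siegel_tukey_ranks(n: int) -> np.ndarray:
    """Alternating-extreme ranks for a sorted pooled sample of size n:
    rank 1 to the smallest, 2 and 3 to the two largest, 4 and 5 to the next
    two smallest, continuing inward."""
    order = np.empty(n, dtype=int)  # order[r-1] = sorted index receiving rank r
    lo, hi = 0, n - 1
    r = 0
    take_low = True
    first = True
    while lo <= hi:
        count = 1 if first else 2
        first = False
        for _ in range(count):
            if lo > hi:
                break
            if take_low:
                order[r] = lo
                lo += 1
            else:
                order[r] = hi
                hi -= 1
            r += 1
        take_low = not take_low
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def siegel_tukey(x, y) -> TestResult:
    """Two-sided Siegel-Tukey dispersion test.

    The pooled sample is sorted and given alternating-extreme ranks (ties
    receive midranks); a Wilcoxon rank-sum normal approximation with tie
    correction is applied to those ranks.  The more dispersed sample
    collects the smaller ranks.  Medians are not aligned first, so the test
    conflates location and scale when the medians differ.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least two values")
    pooled = np.concatenate([x, y])
    n = nx + ny
    sort_idx = np.argsort(pooled, kind="mergesort")
    st = np.empty(n, dtype=float)
    st[sort_idx] = siegel_tukey_ranks(n)
    # midranks for tied values
    vals, inv = np.unique(pooled, return_inverse=True)
    for v in range(len(vals)):
        tied = inv == v
        if tied.sum() > 1:
            st[tied] = st[tied].mean()
    w = st[:nx].sum()
    mean_w = nx * (n + 1) / 2.0
    tie_sizes = np.bincount(inv)
    tie_term = (tie_sizes ** 3 - tie_sizes).sum()
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return TestResult(0.0, 1.0, "siegel_tukey", nx, ny)
    z = (w - mean_w) / np.sqrt(var_w)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), "siegel_tukey", nx, ny)
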