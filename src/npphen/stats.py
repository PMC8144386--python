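"""Group-comparison and correlation statistics for phenotype tables.

Covers the tests used to contrast preterm and term donors: the
Mann-Whitney U test (exact by full enumeration for small tie-free samples,
normal approximation with tie and continuity corrections otherwise), the
two-sample t test (Student pooled by default, Welch optional), Pearson
correlation, and mean +/- SEM group summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "two_sample_t",
    "pearson",
    "mean_sem",
]

#: largest group size for which the exact Mann-Whitney null is enumerated
EXACT_MAX_N = 8


@dataclass
class GroupComparison:
    """Outcome of one two-group test."""

    method: str
    statistic: float
    pvalue: float
    n_x: int
    n_y: int
    notes: str = ""


def mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, SEM, n) with SEM = sample SD / sqrt(n); SEM is NaN for n < 2."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    sem = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return float(x.mean()), sem, n


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U_x, U_y) with ties counted half to each side."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n_x, n_y = x.size, y.size
    r_x = ranks[:n_x].sum()
    u_x = r_x - n_x * (n_x + 1) / 2
    return float(u_x), float(n_x * n_y - u_x)


def _exact_u_distribution(values: np.ndarray, n_x: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of U_x by enumerating all group assignments.

    Under the null every split of the observed (tie-free) values into
    groups of sizes n_x and n - n_x is equally likely; U_x for a split is
    the rank sum of the x side minus n_x(n_x+1)/2.
    """
    n = values.size
    counts: dict[float, int] = {}
    offset = n_x * (n_x + 1) / 2
    for positions in combinations(range(n), n_x):
        # positions are 0-based sorted ranks of the x side
        u = sum(positions) + n_x - offset
        counts[u] = counts.get(u, 0) + 1
    us = np.array(sorted(counts))
    freq = np.array([counts[u] for u in us], dtype=float)
    return us, freq / freq.sum()


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The reported statistic is ``min(U_x, U_y)``.  When both groups have at
    most 8 observations and there are no ties (and ``exact`` is not False),
    the two-sided p-value is exact: twice the smaller tail probability of
    the fully enumerated null distribution of U, capped at 1.  Otherwise a
    normal approximation with tie correction and a 0.5 continuity
    correction is used; the method field records which path ran.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([xa, ya])
    has_ties = np.unique(combined).size < combined.size
    u_x, u_y = _u_statistic(xa, ya)
    u = min(u_x, u_y)

    if np.unique(combined).size == 1:
        return GroupComparison(
            "mann-whitney-u (degenerate)", u, 1.0, xa.size, ya.size,
            notes="all values identical in both groups",
        )

    use_exact = (
        exact
        if exact is not None
        else (max(xa.size, ya.size) <= EXACT_MAX_N and not has_ties)
    )
    if use_exact and has_ties:
        raise ValueError("exact Mann-Whitney p requires tie-free data")

    if use_exact:
        us, probs = _exact_u_distribution(combined, xa.size)
        cdf = float(probs[us <= u_x + 1e-9].sum())
        sf = float(probs[us >= u_x - 1e-9].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
        return GroupComparison(
            "mann-whitney-u (exact)", u, p, xa.size, ya.size,
            notes="full enumeration",
        )

    n_x, n_y = xa.size, ya.size
    n = n_x + n_y
    mu = n_x * n_y / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return GroupComparison(
            "mann-whitney-u (degenerate)", u, 1.0, n_x, n_y,
            notes="zero variance under null",
        )
    z = (abs(u_x - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    notes = "normal approximation, continuity correction" + (
        ", tie correction" if has_ties else ""
    )
    return GroupComparison(
        "mann-whitney-u (approx)", u, p, n_x, n_y, notes=notes
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Two-sided two-sample t test (Student pooled; Welch on request).

    When both groups have zero variance and equal means the statistic is 0
    and p = 1 by convention (flagged in the notes).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if xa.var(ddof=1) == 0 and ya.var(ddof=1) == 0:
        if xa.mean() == ya.mean():
            return GroupComparison(
                "welch-t" if welch else "student-t", 0.0, 1.0,
                xa.size, ya.size, notes="zero variance in both groups",
            )
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(xa, ya, equal_var=not welch)
    return GroupComparison(
        "welch-t" if welch else "student-t",
        float(res.statistic),
        float(res.pvalue),
        xa.size,
        ya.size,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value.

    p comes from ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if xa.var() == 0 or ya.var() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)
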