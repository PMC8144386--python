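"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import cmath

import numpy as np
import pytest


def dft_oracle(series: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    """Direct O(N^2) single-sided amplitude spectrum, independent of numpy's FFT.

    Mean-subtracts, then evaluates X_k = sum_t x_t exp(-2*pi*i*k*t/N) for
    k = 1..N//2, scaling 2|X_k|/N (|X_k|/N at the Nyquist bin).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    x = x - x.mean()
    ks = range(1, n // 2 + 1)
    freqs = np.array([k * fps / n for k in ks])
    mags = np.empty(len(freqs))
    for i, k in enumerate(ks):
        acc = 0j
        for t in range(n):
            acc += x[t] * cmath.exp(-2j * cmath.pi * k * t / n)
        mags[i] = 2.0 * abs(acc) / n
    if n % 2 == 0:
        mags[-1] /= 2.0
    return freqs, mags


def mwu_brute_force_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating label assignments.

    Independent of the package's rank-based path: U is computed for every
    assignment by directly counting pairwise wins.  Two-sided p doubles the
    smaller tail of the enumerated U_x distribution, capped at 1.
    """
    from itertools import combinations

    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    counts: dict[int, int] = {}
    for idx in combinations(range(len(pooled)), n_x):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        counts[u] = counts.get(u, 0) + 1
    total = sum(counts.values())
    cdf = sum(c for u, c in counts.items() if u <= u_obs) / total
    sf = sum(c for u, c in counts.items() if u >= u_obs) / total
    return min(1.0, 2.0 * min(cdf, sf))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210524)
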