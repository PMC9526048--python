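"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
ranking is done by explicit sorting, Kendall's tau by O(n^2) pair counting,
ANOVA by raw sums of squares, OLS by the normal equations, and window means
by per-bp expansion.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhoscape.core import IntervalRateMap, WindowedTrack


# ---------------------------------------------------------------------------
# brute-force statistical oracles
# ---------------------------------------------------------------------------

def average_ranks(x: np.ndarray) -> np.ndarray:
    """Midranks computed by explicit sorting (no scipy)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Pearson correlation of midranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def brute_kendall_b(x, y) -> float:
    """Tau-b by O(n^2) concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v) -> float:
    _vals, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) / 2 for c in counts))


def brute_anova_f(groups) -> float:
    """One-way F from raw sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_vals)
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def brute_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients from the normal equations (X already includes intercept)."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def brute_window_means(rate_map: IntervalRateMap, window_bp: int) -> np.ndarray:
    """Window means by expanding the map to one rho value per bp."""
    span = int(rate_map.ends[-1])
    per_bp = np.full(span, np.nan)
    for s, e, r in zip(rate_map.starts, rate_map.ends, rate_map.rho):
        per_bp[s:e] = r
    n_win = int(np.ceil(span / window_bp))
    out = np.full(n_win, np.nan)
    for w in range(n_win):
        chunk = per_bp[w * window_bp:(w + 1) * window_bp]
        covered = chunk[~np.isnan(chunk)]
        if len(covered):
            out[w] = covered.mean()
    return out


# ---------------------------------------------------------------------------
# random map / track builders
# ---------------------------------------------------------------------------

def random_interval_map(rng: np.random.Generator, n_intervals: int = 50,
                        arm: str = "2L", gaps: bool = False) -> IntervalRateMap:
    lengths = rng.integers(50, 3000, size=n_intervals)
    gaps_bp = rng.integers(0, 500, size=n_intervals) if gaps else np.zeros(n_intervals, dtype=int)
    starts = np.zeros(n_intervals, dtype=np.int64)
    pos = int(rng.integers(0, 100))
    ends = np.zeros(n_intervals, dtype=np.int64)
    for i in range(n_intervals):
        pos += int(gaps_bp[i])
        starts[i] = pos
        pos += int(lengths[i])
        ends[i] = pos
    rho = rng.gamma(2.0, 0.005, size=n_intervals)
    return IntervalRateMap(arm=arm, population="Cold", starts=starts, ends=ends, rho=rho)


def constant_track(value: float, n_bins: int = 80, window_bp: int = 25_000,
                   arm: str = "2L", units: str = "rho/bp") -> WindowedTrack:
    return WindowedTrack(arm=arm, window_bp=window_bp,
                         values=np.full(n_bins, value), units=units)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
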