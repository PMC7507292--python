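"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: exact
rational arithmetic for Fisher's test, a hand-rolled BH step-up, a naive
all-pairs interval scan, full rank-arrangement enumeration for the
rank-sum test, and a minimal NIPALS PLS1.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration (exact)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, col1 - (n - row1)), min(col1, row1)
    denom = math.comb(n, row1)
    pmf = {k: Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs)


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values, written out as the textbook step-up."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * m / rank_from_top
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


def brute_force_overlaps(intervals_a, intervals_b, min_overlap=1):
    """All-pairs interval overlap (0-based half-open): list of (i, j)."""
    hits = []
    for i, (ca, sa, ea) in enumerate(intervals_a):
        for j, (cb, sb, eb) in enumerate(intervals_b):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap:
                hits.append((i, j))
    return hits


def wilcoxon_exact_enumeration(a, b) -> float:
    """Two-sided rank-sum p by enumerating every assignment of ranks."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # tie-free inputs only
    n1 = len(a)
    w_obs = sum(ranks[v] for v in a)
    all_ranks = list(ranks.values())
    mean_w = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(all_ranks, n1):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def nipals_pls1(X: np.ndarray, y: np.ndarray):
    """First-component NIPALS PLS1 on centered data: returns (w, t, p, q)."""
    w = X.T @ y
    w = w / np.sqrt(w @ w)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    return w, t, p, q
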