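"""Independent brute-force / enumeration oracles used by the test suite.

Deliberately naive implementations (sum-of-products, step-up scan, full
enumeration with exact rationals) kept separate from the package code paths
they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np


def pearson_oracle(x, y) -> float:
    """Textbook sum-of-products Pearson correlation."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / sqrt(sxx * syy)


def bh_oracle(pvals) -> list[float]:
    """Direct step-up BH: q_i = min over p_(j) >= p_i of p_(j) * n / rank(j)."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [None] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        q[i] = running
    return q


def wilcoxon_exact_oracle(x, y) -> Fraction:
    """Two-sided rank-sum p by full enumeration, exact rational, midranks."""
    x = list(x)
    y = list(y)
    nx = len(x)
    combined = x + y
    n = len(combined)
    # midranks
    order = sorted(range(n), key=lambda i: combined[i])
    ranks = [Fraction(0)] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        avg = Fraction(sum(range(i + 1, j + 2)), j - i + 1)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(ranks[:nx])
    mu = Fraction(nx * (n + 1), 2)
    dev = abs(w_obs - mu)
    extreme = 0
    total = 0
    for idx in combinations(range(n), nx):
        total += 1
        w = sum(ranks[i] for i in idx)
        if abs(w - mu) >= dev:
            extreme += 1
    return Fraction(extreme, total)


def hypergeom_tail_oracle(overlap: int, population: int, successes: int,
                          draws: int) -> Fraction:
    """P(X >= overlap) by exact rational summation of the pmf."""
    denom = comb(population, draws)
    total = Fraction(0)
    for k in range(overlap, min(successes, draws) + 1):
        if draws - k > population - successes:
            continue
        total += Fraction(
            comb(successes, k) * comb(population - successes, draws - k), denom
        )
    return total


def pairwise_r_oracle(wide: np.ndarray, i: int, j: int) -> float:
    """Pairwise-complete Pearson between two columns of a matrix."""
    a, b = wide[:, i], wide[:, j]
    mask = ~np.isnan(a) & ~np.isnan(b)
    return pearson_oracle(a[mask], b[mask])
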