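"""Brute-force enumeration oracles, independent of the implementations."""

from itertools import combinations, permutations

import numpy as np


def ranksum_enumeration(a, b, alternative="two-sided"):
    """Exact Mann-Whitney U p-value by enumerating every group assignment.

    Assumes no ties.  ``U`` counts pairs (a_i, b_j) with a_i > b_j; the
    two-sided p doubles the smaller tail (capped at 1), matching the exact
    convention of standard implementations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = a.size

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        return sum((x > y) for x in aa for y in bb)

    u_obs = sum((x > y) for x in a for y in b)
    us = [u_stat(idx) for idx in combinations(range(pooled.size), n)]
    us = np.asarray(us)
    p_greater = np.mean(us >= u_obs)
    p_less = np.mean(us <= u_obs)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    return float(min(1.0, 2.0 * min(p_greater, p_less)))


def spearman_enumeration(x, y):
    """Exact two-sided Spearman p by enumerating all rank permutations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0

    def pearson(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in permutations(range(x.size)):
        count += abs(pearson(rx, ry[list(perm)])) >= abs(rho) - 1e-12
        total += 1
    return rho, count / total
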