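"""Brute-force oracles, independent of the package implementation.

Exhaustive enumeration of hypergeometric tails and rank-sum p-values for
small problem sizes; used to pin the fast implementations.
"""

from __future__ import annotations

from itertools import combinations


def hypergeom_tail_enumeration(N: int, M: int, n: int, m: int) -> float:
    """P(overlap >= m) by enumerating every n-subset of an N-item background
    whose first M items are marked."""
    marked = set(range(M))
    total = 0
    hits = 0
    for sel in combinations(range(N), n):
        total += 1
        if len(marked.intersection(sel)) >= m:
            hits += 1
    return hits / total


def rank_sum_p_enumeration(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum p by enumerating all group assignments.

    p = probability, under random assignment of the pooled values to the
    two groups, of a rank sum at least as extreme (two-sided, doubling the
    smaller tail) as observed.  Assumes no ties.
    """
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    observed = sum(ranks[v] for v in x)
    sums = [
        sum(ranks[pooled[i]] for i in idx)
        for idx in combinations(range(len(pooled)), n1)
    ]
    total = len(sums)
    ge = sum(s >= observed for s in sums) / total
    le = sum(s <= observed for s in sums) / total
    return min(1.0, 2.0 * min(ge, le))
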