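"""Independent brute-force reference implementations used only as test
oracles.  These are deliberately written as plain loops, structurally
unlike the vectorized package code they check."""

from __future__ import annotations

import itertools
from math import comb


def ssgsea_bruteforce(values: dict[str, float], gene_set: set[str], alpha: float) -> float:
    """Running-sum enrichment score by direct enumeration: order genes by
    value descending (gene id ascending on ties), rank weights N..1."""
    ordered = sorted(values, key=lambda g: (-values[g], g))
    n = len(ordered)
    members = [g for g in ordered if g in gene_set]
    m = len(members)
    assert 0 < m < n
    denom = 0.0
    for pos, g in enumerate(ordered):
        if g in gene_set:
            denom += float(n - pos) ** alpha
    es = 0.0
    hit_weight = 0.0
    miss_count = 0
    for pos, g in enumerate(ordered):
        if g in gene_set:
            hit_weight += float(n - pos) ** alpha
        else:
            miss_count += 1
        es += hit_weight / denom - miss_count / (n - m)
    return es


def bh_bruteforce(pvalues: list[float]) -> list[float]:
    """Step-up BH by definition: q(p_(i)) = min_{k >= i} m * p_(k) / k."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(indexed):
        candidates = []
        for later_pos in range(rank_pos, m):
            k = later_pos + 1
            candidates.append(m * pvalues[indexed[later_pos]] / k)
        q[idx] = min(1.0, min(candidates))
    return q


def hypergeom_upper_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(|draw ∩ special| >= k) by enumerating every size-n draw from a
    universe of N items of which K are special."""
    universe = list(range(N))
    special = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total
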