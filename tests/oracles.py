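"""Independent brute-force oracles used by the tests.

These deliberately take the slowest, most literal route (per-bp bitmaps,
all-pairs scans, from-definition formulas) so they share no code path
with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np


def bp_set_components(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Ground truth for >=1 bp transitive merging: represent every
    interval as its literal set of base positions, union-find any two
    whose sets intersect, and return each component's envelope.

    Adjacent-but-disjoint intervals ([100,200] and [201,300]) share no
    base and stay separate, unlike a naive occupancy-run scan.
    """
    n = len(intervals)
    bp_sets = [frozenset(range(s, e + 1)) for s, e in intervals]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if not bp_sets[i].isdisjoint(bp_sets[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    envelopes = [
        (min(intervals[i][0] for i in idx), max(intervals[i][1] for i in idx))
        for idx in groups.values()
    ]
    return sorted(envelopes)


def union_bp_bitmap(intervals: list[tuple[int, int]]) -> int:
    """Covered-bp count from a per-bp occupancy bitmap."""
    if not intervals:
        return 0
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    occupied = np.zeros(hi - lo + 1, dtype=bool)
    for s, e in intervals:
        occupied[s - lo : e - lo + 1] = True
    return int(occupied.sum())


def pairs_overlapping(
    a: list[tuple[str, int, int, str]], b: list[tuple[str, int, int, str]]
) -> set[tuple[str, str, int]]:
    """All-pairs quadratic overlap scan; returns (id_a, id_b, overlap_bp)."""
    hits = set()
    for chrom_a, s_a, e_a, id_a in a:
        for chrom_b, s_b, e_b, id_b in b:
            if chrom_a != chrom_b:
                continue
            ov = min(e_a, e_b) - max(s_a, s_b) + 1
            if ov >= 1:
                hits.add((id_a, id_b, ov))
    return hits


def pearson_from_definition(x, y) -> float:
    """Textbook sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def hypergeom_upper_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct combinatorics."""
    total = 0.0
    for i in range(k, min(big_k, n) + 1):
        total += math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
    return total / math.comb(big_n, n)


def vst_by_hand(pop1, pop2) -> float:
    """VST from first principles with denominator-N variances."""
    pop1, pop2 = list(pop1), list(pop2)
    pooled = pop1 + pop2

    def var(v):
        mu = sum(v) / len(v)
        return sum((x - mu) ** 2 for x in v) / len(v)

    v_total = var(pooled)
    if v_total == 0:
        return 0.0
    within = (var(pop1) * len(pop1) + var(pop2) * len(pop2)) / len(pooled)
    return (v_total - within) / v_total
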