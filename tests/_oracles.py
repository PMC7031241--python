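"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: maximum matching is
computed by exhaustive dynamic programming over target subsets, driver
counts by re-running that oracle after node deletion, and two-sided
Fisher p-values by exact hypergeometric enumeration with integer
arithmetic.
"""

from __future__ import annotations

from math import comb
from typing import Dict, Iterable, Set, Tuple


def brute_matching_cardinality(nodes: Iterable[str], edges: Iterable[Tuple[str, str]]) -> int:
    """Exact maximum bipartite matching size of the out/in-copy mapping,
    by DP over subsets of in-copies (feasible for <= ~16 nodes)."""
    names = sorted(set(nodes))
    index = {n: i for i, n in enumerate(names)}
    adj: Dict[int, Set[int]] = {i: set() for i in range(len(names))}
    for u, v in edges:
        adj[index[u]].add(index[v])
    best = {0: 0}
    for u in range(len(names)):
        new = dict(best)
        for mask, val in best.items():
            for t in adj[u]:
                bit = 1 << t
                if not mask & bit:
                    key = mask | bit
                    if new.get(key, -1) < val + 1:
                        new[key] = val + 1
        best = new
    return max(best.values())


def brute_n_d(nodes: Iterable[str], edges: Iterable[Tuple[str, str]]) -> int:
    """Minimum driver count with the max(N - |M|, 1) floor."""
    nodes = set(nodes)
    return max(len(nodes) - brute_matching_cardinality(nodes, edges), 1)


def brute_n_d_after_removal(
    nodes: Iterable[str], edges: Iterable[Tuple[str, str]], removed: str
) -> int:
    nodes = set(nodes) - {removed}
    edges = [(u, v) for u, v in edges if removed not in (u, v)]
    return max(len(nodes) - brute_matching_cardinality(nodes, edges), 1) if nodes else 1


def brute_classify(nodes: Iterable[str], edges: Iterable[Tuple[str, str]]) -> Dict[str, str]:
    nodes = set(nodes)
    edges = list(edges)
    n_d = brute_n_d(nodes, edges)
    out = {}
    for v in nodes:
        nd_removed = brute_n_d_after_removal(nodes, edges, v)
        if nd_removed > n_d:
            out[v] = "indispensable"
        elif nd_removed == n_d:
            out[v] = "neutral"
        else:
            out[v] = "dispensable"
    return out


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities
    no larger than the observed one, using exact integer weights."""
    r, n_total = a + b, a + b + c + d
    c1 = a + c
    lo = max(0, r + c1 - n_total)
    hi = min(r, c1)
    weights = {k: comb(r, k) * comb(n_total - r, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    total = comb(n_total, c1)
    return sum(w for w in weights.values() if w <= observed) / total
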