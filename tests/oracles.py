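"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (exhaustive enumeration, quadratic
scans, full rescans) and shares no code path with the package internals it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def floyd_warshall(nodes, edges):
    """All-pairs hop distances as {(a, b): d}; missing key = unreachable."""
    nodes = list(nodes)
    inf = math.inf
    d = {(a, b): (0 if a == b else inf) for a in nodes for b in nodes}
    for a, b in edges:
        d[(a, b)] = d[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[(i, k)] + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = d[(i, k)] + d[(k, j)]
    return {k: v for k, v in d.items() if v < inf}


def union_find_components(nodes, edges):
    """Connected components via union-find, as a list of frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return [frozenset(c) for c in comps.values()]


def hypergeom_tail_enumerate(N, K, n, k):
    """P(|draw ∩ successes| >= k) by enumerating every n-subset of N items.

    Items 0..K-1 are the successes.  Only feasible for small N.
    """
    hits = total = 0
    for subset in combinations(range(N), n):
        total += 1
        if sum(1 for x in subset if x < K) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_comb(N, K, n, k):
    """Upper tail sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n) via exact integers."""
    denom = math.comb(N, n)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(K, n) + 1))
    return num / denom


def bh_reference(pvals):
    """Quadratic-time Benjamini-Hochberg step-up, independent of statsmodels."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(1.0, pvals[i] * m / rank_from_top)
        running_min = min(running_min, q)
        adjusted[i] = running_min
    return adjusted


def brute_force_diamond(adjacency, seeds, n_iterations):
    """Full-rescan DIAMOnD: recompute every candidate's tail every iteration.

    ``adjacency``: {node: set(neighbors)}.  Tail computed by the exact-integer
    combinatorial sum; ties broken by (p, -ks, k, node) like the package.
    Returns [(iteration, gene, k, ks, p), ...].
    """
    N = len(adjacency)
    module = set(seeds)
    steps = []
    for it in range(1, n_iterations + 1):
        s0 = len(module)
        best = None
        for node in adjacency:
            if node in module:
                continue
            ks = sum(1 for nb in adjacency[node] if nb in module)
            if ks < 1:
                continue
            k = len(adjacency[node])
            p = hypergeom_tail_comb(N, s0, k, ks)
            cand = (p, -ks, k, node)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        p, neg_ks, k, gene = best
        steps.append((it, gene, k, -neg_ks, p))
        module.add(gene)
    return steps
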