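"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and where possible the libraries)
they are checking: Fisher p-values come from exact integer arithmetic,
betweenness from explicit path enumeration or BFS path counting.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (exact rationals).

    Sums C(K,i)*C(N-K,n-i)/C(N,n) over every i in the support whose table
    count does not exceed the observed one (point-probability rule).
    """
    lo, hi = max(0, n + K - N), min(n, K)
    counts = {i: comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1)}
    obs = counts[k]
    total = sum(c for c in counts.values() if c <= obs)
    return float(Fraction(total, comb(N, n)))


def fisher_two_sided_all_k(K: int, n: int, N: int) -> list[float]:
    """Exact two-sided p for every k in the support at fixed margins."""
    lo, hi = max(0, n + K - N), min(n, K)
    counts = [comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1)]
    denom = comb(N, n)
    return [
        float(Fraction(sum(c for c in counts if c <= obs), denom)) for obs in counts
    ]


def betweenness_by_simple_paths(adjacency: dict) -> dict:
    """Normalized betweenness by explicit enumeration of all simple paths.

    ``adjacency``: node -> set of neighbors (undirected).  Only feasible for
    tiny graphs; completely independent of any shortest-path library code.
    """
    nodes = sorted(adjacency)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}

    def all_simple_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adjacency[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_simple_paths(s, t)
            if not paths:
                continue
            d = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == d]
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                score[v] += through / len(shortest)
    if n > 2:
        norm = 2.0 / ((n - 1) * (n - 2))
    else:
        norm = 0.0
    return {v: score[v] * norm for v in nodes}


def betweenness_by_path_counts(adjacency: dict) -> dict:
    """Normalized betweenness via BFS distances and shortest-path counts.

    Uses the combinatorial identity: the number of shortest s-t paths through
    v equals sigma(s,v)*sigma(v,t) when d(s,v)+d(v,t)=d(s,t).  No Brandes
    dependency accumulation.
    """
    nodes = sorted(adjacency)
    n = len(nodes)
    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adjacency[v]:
                    if w not in d:
                        d[w] = d[v] + 1
                        sig[w] = 0
                        nxt.append(w)
                    if d[w] == d[v] + 1:
                        sig[w] += sig[v]
            frontier = nxt
        dist[s] = d
        sigma[s] = sig
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            dst = dist[s][t]
            total = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == dst:
                    score[v] += sigma[s][v] * sigma[t][v] / total
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return {v: score[v] * norm for v in nodes}
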