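"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths (and the libraries
standing behind them): exact rational arithmetic for the hypergeometric
tail, hand-coded step formulas for the corrections, all-pairs BFS path
enumeration for betweenness, and from-scratch average-linkage recomputation
for UPGMA merge heights.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction


def fisher_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Upper hypergeometric tail as an exact rational."""
    total = math.comb(N, n)
    s = Fraction(0)
    for j in range(k, min(n, K) + 1):
        s += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return s


def bonferroni_oracle(ps):
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def holm_oracle(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * ps[i]))
        adj[i] = running
    return adj


def bh_oracle(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, min(1.0, m * ps[i] / (rank + 1)))
        adj[i] = running
    return adj


def betweenness_naive(nodes, edges):
    """Unnormalized betweenness by explicit shortest-path enumeration.

    Undirected, endpoints excluded, each unordered pair counted once,
    fractional credit across equal-length shortest paths.
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        dist = {s: 0}
        preds = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    preds[w] = [u]
                    q.append(w)
                elif dist[w] == dist[u] + 1:
                    preds[w].append(u)
        if t not in dist:
            return []
        paths = []

        def back(v, tail):
            if v == s:
                paths.append([s] + tail)
                return
            for p in preds[v]:
                back(p, [v] + tail)

        back(t, [])
        return paths

    bc = {v: 0.0 for v in nodes}
    ns = sorted(nodes, key=str)
    for i, s in enumerate(ns):
        for t in ns[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += share
    return bc


def upgma_heights_naive(d):
    """Merge heights recomputed from the original distance matrix.

    At every step the average inter-cluster distance is recomputed from
    scratch over all leaf pairs; ties broken by smallest (min-leaf,
    min-leaf) pair.  Returns the sorted list of merge heights.
    """
    n = len(d)
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                ca, cb = clusters[x], clusters[y]
                avg = sum(d[i][j] for i in ca for j in cb) / (len(ca) * len(cb))
                key = (avg, min(min(ca), min(cb)), max(min(ca), min(cb)))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (avg, _, _), x, y = best
        heights.append(avg)
        merged = clusters[x] | clusters[y]
        clusters = [c for z, c in enumerate(clusters) if z not in (x, y)] + [merged]
    return heights
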