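"""Independent brute-force oracles used only by the test suite.

Deliberately naive and independent of the package's code paths:
- centralities via explicit shortest-path enumeration, a dense
  eigendecomposition, and triple-loop triangle counting;
- hypergeometric tails via exact rational arithmetic;
- Benjamini-Hochberg by the hand-written step-up recursion.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction
from itertools import combinations

import numpy as np


def _bfs(adj: dict, source):
    dist = {source: 0}
    order = [source]
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                order.append(v)
                queue.append(v)
    return dist


def _all_shortest_paths(adj: dict, dist: dict, s, t):
    """Enumerate every shortest s-t path by DFS over the distance DAG."""
    if t not in dist:
        return
    stack = [(t, [t])]
    while stack:
        node, path = stack.pop()
        if node == s:
            yield path[::-1]
            continue
        for p in adj[node]:
            if p in dist and dist[p] == dist[node] - 1:
                stack.append((p, path + [p]))


def brute_centralities(nodes, edges) -> dict[str, dict]:
    """All six measures by exhaustive computation. Suitable for n <= ~30."""
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)

    dc = {n: len(adj[n]) for n in nodes}

    # betweenness + closeness from per-source BFS distances
    bc = {n: 0.0 for n in nodes}
    cc = {}
    dists = {s: _bfs(adj, s) for s in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(_all_shortest_paths(adj, dists[s], s, t))
        if not paths:
            continue
        sigma = len(paths)
        through = {n: 0 for n in nodes}
        for path in paths:
            for v in path[1:-1]:
                through[v] += 1
        for v in nodes:
            if through[v]:
                bc[v] += through[v] / sigma
    for v in nodes:
        reach = dists[v]
        total = sum(reach.values())
        cc[v] = (len(reach) - 1) / total if total > 0 else 0.0

    # eigenvector per connected component via dense eigendecomposition
    ec = {}
    unseen = set(nodes)
    while unseen:
        start = next(iter(sorted(unseen)))
        comp = sorted(_bfs(adj, start))
        unseen -= set(comp)
        if len(comp) == 1:
            ec[comp[0]] = 0.0
            continue
        index = {n: i for i, n in enumerate(comp)}
        a = np.zeros((len(comp), len(comp)))
        for u in comp:
            for v in adj[u]:
                a[index[u], index[v]] = 1.0
        w, vecs = np.linalg.eigh(a)
        vec = np.abs(vecs[:, int(np.argmax(w))])
        vec = vec / np.linalg.norm(vec)
        for n in comp:
            ec[n] = float(vec[index[n]])

    # NC via triple-loop triangle counts
    nc = {n: 0.0 for n in nodes}
    for u, v in combinations(nodes, 2):
        if v not in adj[u]:
            continue
        z = sum(1 for w_ in nodes if w_ in adj[u] and w_ in adj[v])
        denom = min(dc[u] - 1, dc[v] - 1)
        if denom > 0:
            nc[u] += z / denom
            nc[v] += z / denom

    lac = {}
    for n in nodes:
        nbrs = adj[n]
        if not nbrs:
            lac[n] = 0.0
            continue
        degs = [sum(1 for w_ in nbrs if w_ in adj[u]) for u in nbrs]
        lac[n] = sum(degs) / len(nbrs)

    return {"dc": {n: float(dc[n]) for n in nodes}, "bc": bc, "cc": cc,
            "ec": ec, "nc": nc, "lac": lac}


def exact_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, classic step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted
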