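"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles on adjacency dicts —
no networkx, no package code — so agreement is a genuine two-route check.
"""

from __future__ import annotations

import math
from itertools import combinations


def adjacency(edges, nodes=()):
    """Adjacency dict from an undirected edge list."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set())
        adj.setdefault(v, set())
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    """Hop distances from source to every reachable node (layer expansion)."""
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def min_distance_to_set(adj, source, targets):
    if source in targets:
        return 0.0
    dist = bfs_distances(adj, source)
    best = math.inf
    for t in targets:
        if t in dist and dist[t] < best:
            best = float(dist[t])
    return best


def all_shortest_paths(adj, s, t):
    """Every shortest s→t path, rebuilt backwards from BFS distances."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in adj[v]:
            if dist.get(u) == dist[v] - 1:
                back(u, [v] + suffix)

    back(t, [])
    return paths


def brute_betweenness(adj):
    """Normalized shortest-path betweenness by full path enumeration."""
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    denom = (n - 1) * (n - 2) / 2
    if denom > 0:
        for v in nodes:
            score[v] /= denom
    return score


def brute_harmonic_closeness(adj):
    """Mean inverse distance to the other nodes; unreachable contributes 0."""
    nodes = sorted(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        total = sum(1.0 / d for u, d in dist.items() if u != v and d > 0)
        out[v] = total / (n - 1) if n > 1 else 0.0
    return out


def brute_pagerank(adj, damping=0.85, tol=1e-12, max_iter=10000):
    """Power iteration on the Google matrix; dangling mass spread uniformly."""
    nodes = sorted(adj)
    n = len(nodes)
    p = {v: 1.0 / n for v in nodes}
    for _ in range(max_iter):
        dangling = sum(p[v] for v in nodes if not adj[v])
        new = {}
        for v in nodes:
            incoming = sum(p[u] / len(adj[u]) for u in adj[v])
            new[v] = (1 - damping) / n + damping * (incoming + dangling / n)
        err = sum(abs(new[v] - p[v]) for v in nodes)
        p = new
        if err < n * tol:
            break
    return p


def brute_topology_score(adj, ip, genes1, genes2, decay_rate=1.0):
    """Literal evaluation of the dual-term TS formula."""

    def term(own, other):
        den = sum(ip[g] for g in own)
        if den == 0:
            return 0.0
        num = 0.0
        for g in own:
            d = min_distance_to_set(adj, g, other)
            if math.isfinite(d):
                num += ip[g] * math.exp(-decay_rate * d)
        return num / den

    return 0.5 * (term(genes1, genes2) + term(genes2, genes1))


def brute_agent_score(ph1, ph2, sim):
    """Mean similarity over the full phenotype cross product."""
    if not ph1 or not ph2:
        return 1.0
    vals = [sim[p][q] for p in ph1 for q in ph2]
    return sum(vals) / len(vals)
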