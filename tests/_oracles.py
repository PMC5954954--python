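"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive path enumeration,
integer combinatorics, peel-based core decomposition — and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


# ---------------------------------------------------------------------------
# graph helpers on plain adjacency dicts
# ---------------------------------------------------------------------------

def adjacency(edges) -> dict:
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bfs_distances(adj, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def all_shortest_paths(adj, s, t):
    """Enumerate every shortest s–t path by DFS over the BFS predecessor DAG."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return
    preds: dict = {}
    for u in dist:
        for v in adj[u]:
            if v in dist and dist[v] == dist[u] + 1:
                preds.setdefault(v, []).append(u)

    def walk(node):
        if node == s:
            yield [s]
            return
        for p in preds.get(node, []):
            for path in walk(p):
                yield path + [node]

    yield from walk(t)


def brute_betweenness(nodes, edges) -> dict:
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    adj = adjacency(edges)
    nodes = list(nodes)
    n = len(nodes)
    acc = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if s not in adj or t not in adj:
            continue
        paths = list(all_shortest_paths(adj, s, t))
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            acc[v] += Fraction(through, sigma)
    norm = Fraction((n - 1) * (n - 2), 2) if n > 2 else Fraction(1)
    return {v: float(acc[v] / norm) for v in nodes}


def brute_closeness(nodes, edges, convention="normalized") -> dict:
    """Closeness within each connected component by hand-rolled BFS."""
    adj = adjacency(edges)
    out = {}
    for v in nodes:
        if v not in adj:
            out[v] = 0.0
            continue
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        n_comp = len(dist)
        if total == 0:
            out[v] = 0.0
        elif convention == "normalized":
            out[v] = (n_comp - 1) / total
        else:
            out[v] = 1.0 / total
    return out


def brute_degree(nodes, edges) -> dict:
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


# ---------------------------------------------------------------------------
# k-cores and MCODE vertex weights, by peeling
# ---------------------------------------------------------------------------

def brute_core_numbers(nodes, edges) -> dict:
    """Core numbers by definition: v's core number is the largest k such that
    v survives repeated deletion of all vertices with degree < k."""
    result = {v: 0 for v in nodes}
    k = 1
    while True:
        adj = adjacency(edges)
        for v in nodes:
            adj.setdefault(v, set())
        changed = True
        while changed:
            low = [v for v in adj if len(adj[v]) < k]
            changed = bool(low)
            for v in low:
                for nb in adj[v]:
                    adj[nb].discard(v)
                del adj[v]
        if not adj:
            break
        for v in adj:
            result[v] = k
        k += 1
    return result


def brute_mcode_weight(nodes, edges, vertex, degree_cutoff=2) -> float:
    """MCODE vertex weight evaluated straight from its definition."""
    adj = adjacency(edges)
    if len(adj.get(vertex, ())) < degree_cutoff:
        return 0.0
    closed = {vertex} | adj[vertex]
    sub_edges = [(a, b) for a, b in edges if a in closed and b in closed]
    cores = brute_core_numbers(closed, sub_edges)
    k_max = max(cores.values())
    if k_max == 0:
        return 0.0
    core_nodes = {v for v, c in cores.items() if c >= k_max}
    core_edges = [(a, b) for a, b in sub_edges if a in core_nodes and b in core_nodes]
    n = len(core_nodes)
    density = 2 * len(core_edges) / (n * (n - 1)) if n > 1 else 0.0
    return k_max * density


# ---------------------------------------------------------------------------
# exact hypergeometric tail
# ---------------------------------------------------------------------------

def exact_hypergeom_tail(k, K, n, N) -> Fraction:
    """P(X >= k) as an exact rational via integer binomials."""
    total = comb(N, n)
    s = 0
    for j in range(k, min(K, n) + 1):
        s += comb(K, j) * comb(N - K, n - j)
    return Fraction(s, total)


def brute_bh(p_values):
    """Benjamini–Hochberg step-up, written from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = min(1.0, p_values[i] * m / rank_from_end)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


# ---------------------------------------------------------------------------
# naive two-pass neighbourhood expansion
# ---------------------------------------------------------------------------

def brute_expand(seeds, edges, min_seed_links):
    """Node set of the seed-expansion network by a naive double loop."""
    seeds = set(seeds)
    nodes = {n for e in edges for n in e}
    keep = set()
    for v in nodes:
        if v in seeds:
            keep.add(v)
            continue
        links = sum(1 for a, b in edges if (a == v and b in seeds) or (b == v and a in seeds))
        if links >= min_seed_links:
            keep.add(v)
    kept_edges = [(a, b) for a, b in edges if a in keep and b in keep]
    with_degree = {n for e in kept_edges for n in e}
    return keep & with_degree, kept_edges
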