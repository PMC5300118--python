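"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the implementation's algorithms: distances come
from Floyd-Warshall on the adjacency matrix, betweenness from explicit
enumeration of every shortest path, projections from a double loop over
vertex pairs.
"""

from itertools import combinations

import numpy as np

INF = float("inf")


def _index(g):
    nodes = sorted(g.nodes)
    return nodes, {v: i for i, v in enumerate(nodes)}


def floyd_warshall(g):
    nodes, idx = _index(g)
    n = len(nodes)
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges():
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return nodes, d


def brute_degree(g):
    return {v: sum(1 for _ in g[v]) for v in g}


def brute_closeness(g):
    nodes, d = floyd_warshall(g)
    out = {}
    for i, v in enumerate(nodes):
        reach = [d[i, j] for j in range(len(nodes)) if j != i and d[i, j] < INF]
        out[v] = (sum(reach) / len(reach)) if reach else None
    return out


def _all_shortest_paths(g, idx, d, s, t):
    """Enumerate every shortest s-t path by distance-guided backtracking."""
    target_len = d[idx[s], idx[t]]
    if target_len == INF:
        return []
    paths = []

    def walk(v, path):
        if v == t:
            paths.append(list(path))
            return
        for w in g[v]:
            # path holds s..v, so d(s,v) == len(path) - 1; w extends a
            # shortest path iff d(s,w) == len(path) and w lies on a geodesic
            if d[idx[s], idx[w]] == len(path) and \
               d[idx[w], idx[t]] == target_len - len(path):
                path.append(w)
                walk(w, path)
                path.pop()

    walk(s, [s])
    return paths


def brute_betweenness(g):
    """Unnormalized betweenness: each unordered pair counted once."""
    nodes, d = floyd_warshall(g)
    idx = {v: i for i, v in enumerate(nodes)}
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(g, idx, d, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def brute_project(side_sets, vertices):
    """Shared-counterpart projection by a double loop over vertex pairs."""
    edges = {}
    verts = sorted(vertices)
    for u, v in combinations(verts, 2):
        shared = sum(1 for members in side_sets.values() if u in members and v in members)
        if shared:
            edges[(u, v)] = shared
    return edges
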