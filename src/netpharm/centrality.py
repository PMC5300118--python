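"""Degree, betweenness and closeness centrality, and ranked target reports.

All three indicators are computed on the simple undirected graph, ignoring
projection weights. Conventions:

* degree — neighbor count (isolates get 0);
* betweenness — unnormalized Brandes accumulation over unordered vertex
  pairs, endpoints excluded; disconnected pairs contribute 0;
* closeness — the *distance-like* convention: the mean geodesic distance
  from a vertex to the vertices it can reach (lower = more central);
  undefined for a vertex with no reachable counterpart, and recorded as
  missing rather than 0, since 0 would invert the ordering.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from math import isnan

import networkx as nx
import pandas as pd


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    return {v: g.degree(v) for v in g}


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Brandes single-source accumulation on the unweighted graph.

    Each unordered pair (s, t) with s != v != t contributes
    sigma_st(v) / sigma_st once.
    """
    bc = dict.fromkeys(g, 0.0)
    for s in g:
        stack: list = []
        preds: dict = {v: [] for v in g}
        sigma = dict.fromkeys(g, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(g, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in g[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(g, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def closeness_centrality(g: nx.Graph) -> dict[str, float | None]:
    """Mean BFS distance to reachable vertices; None when none are reachable."""
    out: dict[str, float | None] = {}
    for s in g:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        reach = len(dist) - 1
        out[s] = (sum(dist.values()) / reach) if reach else None
    return out


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    """All three indicators for every vertex, indexed by symbol.

    Undefined closeness is NaN.
    """
    deg = degree_centrality(g)
    bet = betweenness_centrality(g)
    clo = closeness_centrality(g)
    idx = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in idx],
            "betweenness": [bet[v] for v in idx],
            "closeness": [clo[v] if clo[v] is not None else float("nan") for v in idx],
        },
        index=pd.Index(idx, name="symbol"),
    )


@dataclass
class RankedTargets:
    """Top-k lists per indicator plus the rank-sum consensus ordering."""

    by_degree: list[str]
    by_betweenness: list[str]
    by_closeness: list[str]
    consensus: list[str]
    rank_sums: dict[str, int]


def _full_ranking(items: list[tuple[str, float]], ascending: bool) -> list[str]:
    # ties broken by ascending symbol text
    return [
        s for s, _ in sorted(items, key=lambda p: (p[1] if ascending else -p[1], p[0]))
    ]


def rank_targets(table: pd.DataFrame, k: int = 10) -> RankedTargets:
    """Rank vertices by each indicator and by ascending rank-sum consensus.

    Degree and betweenness descending, closeness ascending (vertices with
    undefined closeness are excluded from the closeness list and take the
    worst closeness rank in the consensus). Ties break on symbol text.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    deg_rank = _full_ranking(
        [(s, float(table.at[s, "degree"])) for s in table.index], ascending=False
    )
    bet_rank = _full_ranking(
        [(s, float(table.at[s, "betweenness"])) for s in table.index], ascending=False
    )
    clo_defined = [
        (s, float(table.at[s, "closeness"]))
        for s in table.index
        if not isnan(float(table.at[s, "closeness"]))
    ]
    clo_rank = _full_ranking(clo_defined, ascending=True)

    worst_clo = len(clo_rank) + 1
    pos = {
        s: {"degree": i + 1}
        for i, s in enumerate(deg_rank)
    }
    for i, s in enumerate(bet_rank):
        pos[s]["betweenness"] = i + 1
    for s in table.index:
        pos[s]["closeness"] = worst_clo
    for i, s in enumerate(clo_rank):
        pos[s]["closeness"] = i + 1
    rank_sums = {s: sum(pos[s].values()) for s in table.index}
    consensus = sorted(table.index, key=lambda s: (rank_sums[s], s))
    return RankedTargets(
        by_degree=deg_rank[:k],
        by_betweenness=bet_rank[:k],
        by_closeness=clo_rank[:k],
        consensus=list(consensus[:k]),
        rank_sums=rank_sums,
    )
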