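"""Bipartite drug-target networks, one-mode projections, and the layered master network.

A bipartite network links source entities (ingredients or drugs) to target
proteins. Projecting onto the target side yields the target-protein (TP)
network: two targets are adjacent iff at least one common source acts on
both, with the number of shared sources as the edge weight. Per-dataset TP
networks are integrated into a master network whose edges are labeled by
origin: specific to either formula, shared by both, or drug-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .core import SourceDataset

MASTER_LAYERS = ("xzd_only", "gxbd_only", "formula_overlap", "drug")


@dataclass
class BipartiteGraph:
    """Sources on one side, targets on the other; edges only across sides."""

    sources: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)  # (source, target)


@dataclass
class MasterNetwork:
    """Layered union of the per-dataset target projections.

    ``flags`` maps each target symbol to its (in_xzd, in_gxbd, in_drug)
    membership triple. The three formula layers partition the union of the
    two formula edge sets; the drug layer is stored separately, so an edge
    pair may appear in both a formula layer and the drug layer.
    """

    flags: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)
    layers: dict[str, nx.Graph] = field(
        default_factory=lambda: {layer: nx.Graph() for layer in MASTER_LAYERS}
    )

    def formula_graph(self, include_drug_layer: bool = False) -> nx.Graph:
        """Combined formula TP network over all formula targets.

        The union of the xzd_only, gxbd_only and formula_overlap layers,
        with every formula-member vertex present (including isolates).
        With ``include_drug_layer`` the drug layer's edges are merged in as
        well (weights added) and drug-only vertices join the vertex set.
        """
        g = nx.Graph()
        for sym, (in_x, in_g, _) in self.flags.items():
            if in_x or in_g:
                g.add_node(sym)
        which = ["xzd_only", "gxbd_only", "formula_overlap"]
        if include_drug_layer:
            which.append("drug")
            for sym, (_, _, in_d) in self.flags.items():
                if in_d:
                    g.add_node(sym)
        for layer in which:
            for u, v, data in self.layers[layer].edges(data=True):
                w = int(data.get("weight", 1))
                if g.has_edge(u, v):
                    g[u][v]["weight"] += w
                else:
                    g.add_edge(u, v, weight=w)
        return g


def build_bipartite(dataset: SourceDataset) -> BipartiteGraph:
    """One edge per distinct (source, target) link; empty dataset is allowed."""
    bg = BipartiteGraph()
    for sid, targets in dataset.links.items():
        bg.sources.add(sid)
        for t in targets:
            bg.targets.add(t)
            bg.edges.add((sid, t))
    return bg


def _project(side_sets: dict[str, set[str]], vertices: set[str]) -> nx.Graph:
    """One-mode projection: weight = number of counterparts shared by a pair."""
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for members in side_sets.values():
        for u, v in combinations(sorted(members), 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


def project_targets(bg: BipartiteGraph) -> nx.Graph:
    """Target-side projection; isolated targets are retained."""
    by_source: dict[str, set[str]] = {}
    for s, t in bg.edges:
        by_source.setdefault(s, set()).add(t)
    return _project(by_source, set(bg.targets))


def project_sources(bg: BipartiteGraph) -> nx.Graph:
    """Source-side projection: two sources are adjacent iff they share a target."""
    by_target: dict[str, set[str]] = {}
    for s, t in bg.edges:
        by_target.setdefault(t, set()).add(s)
    return _project(by_target, set(bg.sources))


def integrate_master(
    tp_xzd: nx.Graph,
    tp_gxbd: nx.Graph,
    tp_drug: nx.Graph,
    universes: tuple[set[str], set[str], set[str]],
) -> MasterNetwork:
    """Integrate the three target projections into the layered master network.

    Formula edges are routed to exactly one of xzd_only / gxbd_only /
    formula_overlap according to which formula projection(s) contain them;
    an overlap edge's weight is the sum of the two formulas' weights. The
    drug projection is stored unchanged as the drug layer.
    """
    xzd_u, gxbd_u, drug_u = universes
    master = MasterNetwork()
    for sym in xzd_u | gxbd_u | drug_u:
        master.flags[sym] = (sym in xzd_u, sym in gxbd_u, sym in drug_u)

    xzd_edges = {frozenset((u, v)): d["weight"] for u, v, d in tp_xzd.edges(data=True)}
    gxbd_edges = {frozenset((u, v)): d["weight"] for u, v, d in tp_gxbd.edges(data=True)}
    for pair, w in xzd_edges.items():
        u, v = sorted(pair)
        if pair in gxbd_edges:
            master.layers["formula_overlap"].add_edge(u, v, weight=w + gxbd_edges[pair])
        else:
            master.layers["xzd_only"].add_edge(u, v, weight=w)
    for pair, w in gxbd_edges.items():
        if pair not in xzd_edges:
            u, v = sorted(pair)
            master.layers["gxbd_only"].add_edge(u, v, weight=w)
    for u, v, data in tp_drug.edges(data=True):
        master.layers["drug"].add_edge(u, v, weight=data["weight"])
    return master


def network_summary(g) -> dict:
    """Vertex/edge/isolate counts; per-layer edge counts for a master network.

    Edge counts are unique unordered pairs, not weight sums.
    """
    if isinstance(g, MasterNetwork):
        layer_edges = {layer: gr.number_of_edges() for layer, gr in g.layers.items()}
        vertices = set(g.flags)
        touched = set()
        for gr in g.layers.values():
            touched.update(gr.nodes)
        pairs = set()
        for gr in g.layers.values():
            pairs.update(frozenset(e) for e in gr.edges())
        return {
            "n_vertices": len(vertices),
            "n_edges": len(pairs),
            "n_isolated": len(vertices - touched),
            "layer_edges": layer_edges,
        }
    return {
        "n_vertices": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_isolated": sum(1 for v in g if g.degree(v) == 0),
    }
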