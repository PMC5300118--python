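import random

import networkx as nx
import numpy as np
import pytest

from netpharm import SourceDataset


@pytest.fixture
def tiny_datasets():
    """Three small hand-built datasets with a known membership partition.

    XZD targets {A,B,C,D}, GXBD targets {B,C,E}, drugs target {C,D,F}:
    common_nodrug={B}, common_drug={C}, xzd_only_nodrug={A},
    xzd_only_drug={D}, gxbd_only_nodrug={E}, drug_only={F}.
    """
    xzd = SourceDataset(
        name="XZD", role="formula",
        links={"x1": {"A", "B"}, "x2": {"B", "C", "D"}},
        labels={"x1": "ing-1", "x2": "ing-2"},
    )
    gxbd = SourceDataset(
        name="GXBD", role="formula",
        links={"g1": {"B", "C"}, "g2": {"E"}},
        labels={"g1": "ing-3", "g2": "ing-4"},
    )
    drugs = SourceDataset(
        name="DRUGS", role="drug_set",
        links={"d1": {"C", "D"}, "d2": {"F"}},
        labels={"d1": "drug-1", "d2": "drug-2"},
    )
    return xzd, gxbd, drugs


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph with string labels, isolates retained."""
    rng = random.Random(seed)
    g = nx.Graph()
    labels = [f"v{i:02d}" for i in range(n)]
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(labels[i], labels[j])
    return g


def random_bipartite_links(n_sources: int, n_targets: int, p: float, seed: int):
    """Random source->target link sets; every source keeps >= 1 link."""
    rng = np.random.default_rng(seed)
    targets = [f"T{j:02d}" for j in range(n_targets)]
    links = {}
    for i in range(n_sources):
        picked = {t for t in targets if rng.random() < p}
        if not picked:
            picked = {targets[int(rng.integers(n_targets))]}
        links[f"s{i:02d}"] = picked
    return links, targets
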