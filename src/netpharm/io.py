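"""Readers and writers for interaction tables and network exports.

Canonical input is a UTF-8 TSV with header ``source_id``, ``source_label``,
``target_symbol`` — one row per interaction. Network outputs are a sorted
edge TSV (``u, v, weight, layer``) and standard GraphML.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import networkx as nx

from .core import SourceDataset, SymbolError, normalize_symbol

if TYPE_CHECKING:  # pragma: no cover
    from .network import MasterNetwork

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("source_id", "source_label", "target_symbol")
EDGE_COLUMNS = ("u", "v", "weight", "layer")


def read_interaction_table(
    path: str | Path,
    name: str,
    role: str,
    compound_namespace: str | None = None,
) -> SourceDataset:
    """Read one interaction TSV into a :class:`SourceDataset`.

    Duplicate ``(source_id, target)`` rows collapse to a single link (the
    number collapsed is logged). Rows whose target symbol is empty after
    normalization are rejected with a warning naming the row. A missing
    required column or a malformed row is a hard error.
    """
    path = Path(path)
    links: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    n_dup = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            if row.get(None) is not None or any(row[c] is None for c in REQUIRED_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed row (wrong field count)")
            sid = row["source_id"].strip()
            if not sid:
                logger.warning("%s:%d: empty source_id, row rejected", path, lineno)
                continue
            try:
                target = normalize_symbol(row["target_symbol"])
            except SymbolError:
                logger.warning("%s:%d: empty target_symbol, row rejected", path, lineno)
                continue
            bucket = links.setdefault(sid, set())
            if target in bucket:
                n_dup += 1
            else:
                bucket.add(target)
            labels.setdefault(sid, row["source_label"].strip() or sid)
    if n_dup:
        logger.info("%s: collapsed %d duplicate link(s)", path, n_dup)
    # sources whose every row was rejected carry no links and are dropped
    links = {s: t for s, t in links.items() if t}
    labels = {s: labels[s] for s in links}
    return SourceDataset(
        name=name, role=role, links=links, labels=labels,
        compound_namespace=compound_namespace,
    )


def write_interaction_table(dataset: SourceDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical TSV dialect, sorted for determinism."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for sid in sorted(dataset.links):
            for target in sorted(dataset.links[sid]):
                writer.writerow([sid, dataset.labels.get(sid, sid), target])


def _edge_rows(graph) -> list[tuple[str, str, int, str]]:
    from .network import MasterNetwork  # local import to avoid a cycle

    rows: list[tuple[str, str, int, str]] = []
    if isinstance(graph, MasterNetwork):
        for layer, g in graph.layers.items():
            for u, v, data in g.edges(data=True):
                a, b = sorted((u, v))
                rows.append((a, b, int(data.get("weight", 1)), layer))
    else:
        for u, v, data in graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, int(data.get("weight", 1)), ""))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    return rows


def write_edge_table(graph, path: str | Path) -> None:
    """Write a projected or master network as a sorted edge TSV.

    Columns are ``u, v, weight, layer`` with ``u < v`` lexicographically;
    the layer column is empty for single-layer graphs.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_COLUMNS)
        writer.writerows(_edge_rows(graph))


def read_edge_table(path: str | Path):
    """Read an edge TSV written by :func:`write_edge_table`.

    Returns a single :class:`networkx.Graph` when every layer field is
    empty, otherwise a ``dict`` mapping layer label to graph.
    """
    path = Path(path)
    by_layer: dict[str, nx.Graph] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            layer = row["layer"] or ""
            g = by_layer.setdefault(layer, nx.Graph())
            g.add_edge(row["u"], row["v"], weight=int(row["weight"]))
    if not by_layer:
        return nx.Graph()
    if set(by_layer) == {""}:
        return by_layer[""]
    return by_layer


def write_graphml(master: "MasterNetwork", path: str | Path) -> None:
    """Export the master network as standard GraphML.

    Vertices carry 0/1 membership flags (``in_xzd``, ``in_gxbd``,
    ``in_drug``) and a ``module`` label; edges carry a ``layer`` attribute.
    Edge pairs present in both a formula layer and the drug layer become
    parallel edges keyed by layer.
    """
    from .core import module_label

    g = nx.MultiGraph()
    for sym, (in_x, in_g, in_d) in sorted(master.flags.items()):
        g.add_node(
            sym,
            in_xzd=int(in_x),
            in_gxbd=int(in_g),
            in_drug=int(in_d),
            module=module_label(in_x, in_g, in_d),
        )
    for layer in sorted(master.layers):
        for u, v, data in master.layers[layer].edges(data=True):
            a, b = sorted((u, v))
            g.add_edge(a, b, key=layer, layer=layer,
                       weight=int(data.get("weight", 1)))
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.MultiGraph:
    return nx.read_graphml(str(path))
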