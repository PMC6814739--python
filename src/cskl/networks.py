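"""Dataset-to-dataset and disease-to-disease similarity networks.

Statistically significant pairwise similarities become edges of a graph
over datasets (one per platform); labelling each dataset with its disease
and counting, for every disease pair, how many significant cross-disease
dataset pairs support it yields a weighted disease-to-disease network that
can be merged across platforms (label-level counting needs no variable
alignment).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .divergence import PairResult
from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "build_dataset_network",
    "build_disease_network",
    "merge_networks",
    "export_network",
    "import_network",
]


def _edge_rank(pair: PairResult) -> tuple:
    # most significant first: ascending q, then c-SKL, then lexicographic IDs
    return (
        pair.q_value if pair.q_value is not None else 1.0,
        pair.cskl,
        pair.key,
    )


def build_dataset_network(
    pairs: list[PairResult],
    top_edges: int | None = None,
    manifest_ids: list[str] | None = None,
    include_isolated: bool = False,
    labels: dict[str, str] | None = None,
    platform_id: str | None = None,
) -> nx.Graph:
    """Graph with datasets as nodes and significant similarities as edges.

    ``top_edges`` keeps only the most significant edges; isolated manifest
    datasets are added as nodes only when ``include_isolated`` is set.
    """
    if top_edges is not None and top_edges <= 0:
        raise ParameterError(f"top_edges must be positive, got {top_edges}")
    ranked = sorted(pairs, key=_edge_rank)
    if top_edges is not None:
        ranked = ranked[:top_edges]
    graph = nx.Graph()
    if platform_id is not None:
        graph.graph["platform_id"] = platform_id
    if include_isolated and manifest_ids:
        for ds in manifest_ids:
            graph.add_node(ds)
    for pair in ranked:
        a, b = pair.key
        if a == b:
            raise ValidationError(f"self-pair {a!r} cannot become an edge")
        attrs = {"cskl": pair.cskl}
        if pair.p_value is not None:
            attrs["p"] = pair.p_value
        if pair.q_value is not None:
            attrs["q"] = pair.q_value
        graph.add_edge(a, b, **attrs)
    if labels:
        for node in graph.nodes:
            if node in labels:
                graph.nodes[node]["disease"] = labels[node]
    return graph


def build_disease_network(
    net: nx.Graph,
    labels: dict[str, str],
    min_weight: int = 1,
) -> nx.Graph:
    """Aggregate a dataset network into a disease network by label counting.

    Every significant dataset pair linking two *different* diseases adds 1
    to that disease pair's edge weight; within-disease pairs are dropped,
    as are edges with an unlabeled endpoint (counted in a log message) and
    final edges below ``min_weight``.  Node degrees are recorded as a node
    attribute.
    """
    if min_weight < 1:
        raise ParameterError(f"min_weight must be >= 1, got {min_weight}")
    disease = nx.Graph()
    unlabeled = 0
    for a, b in net.edges:
        la, lb = labels.get(a), labels.get(b)
        if la is None or lb is None:
            unlabeled += 1
            continue
        if la == lb:
            continue
        if disease.has_edge(la, lb):
            disease[la][lb]["weight"] += 1
        else:
            disease.add_edge(la, lb, weight=1)
    if unlabeled:
        logger.warning("dropped %d dataset edge(s) with unlabeled endpoints", unlabeled)
    drop = [(a, b) for a, b, w in disease.edges(data="weight") if w < min_weight]
    disease.remove_edges_from(drop)
    disease.remove_nodes_from(list(nx.isolates(disease)))
    for node in disease.nodes:
        disease.nodes[node]["degree"] = disease.degree(node)
    return disease


def merge_networks(nets: list[nx.Graph]) -> nx.Graph:
    """Union of disease networks across platforms; edge weights are summed."""
    merged = nx.Graph()
    for net in nets:
        merged.add_nodes_from(net.nodes)
        for a, b, w in net.edges(data="weight", default=1):
            if merged.has_edge(a, b):
                merged[a][b]["weight"] += w
            else:
                merged.add_edge(a, b, weight=w)
    for node in merged.nodes:
        merged.nodes[node]["degree"] = merged.degree(node)
    return merged


def export_network(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML (typed attributes) or a TSV edge list.

    The TSV has columns (source, target, weight) for weighted graphs —
    sorted by descending weight — or (source, target, cskl, q) for dataset
    networks, sorted by ascending q.
    """
    path = Path(path)
    try:
        if fmt == "graphml":
            nx.write_graphml(net, path)
        elif fmt == "edge_list_tsv":
            records = [
                {"source": a, "target": b, **attrs} for a, b, attrs in net.edges(data=True)
            ]
            frame = pd.DataFrame(records, columns=_tsv_columns(net))
            if "weight" in frame.columns:
                frame = frame.sort_values("weight", ascending=False, kind="stable")
            elif "q" in frame.columns:
                frame = frame.sort_values("q", kind="stable")
            frame.to_csv(path, sep="\t", index=False)
        else:
            raise ParameterError(f"unknown export format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write network to {path}: {exc}") from exc


def _tsv_columns(net: nx.Graph) -> list[str]:
    keys: list[str] = []
    for _, _, attrs in net.edges(data=True):
        for key in attrs:
            if key not in keys:
                keys.append(key)
    return ["source", "target", *keys]


def import_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        graph.graph.pop("node_default", None)
        graph.graph.pop("edge_default", None)
        return nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    if fmt == "edge_list_tsv":
        frame = pd.read_csv(path, sep="\t")
        graph = nx.Graph()
        for row in frame.to_dict("records"):
            a, b = str(row.pop("source")), str(row.pop("target"))
            graph.add_edge(a, b, **{k: v for k, v in row.items() if pd.notna(v)})
        return graph
    raise ParameterError(f"unknown import format {fmt!r}")
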