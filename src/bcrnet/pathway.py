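"""Shortest-path subnetwork extraction and hybrid network assembly.

Signal transduction routes are approximated by enumerating *all* shortest
paths (breadth-first, unit edge weights) from the BCR complex node to each
activated signaling intermediate, and from those intermediates to the
shortlisted TFs.  The union of path edges forms a subnetwork; merging the
receptor→intermediate subnetwork, the intermediate→TF subnetwork and the
TF→gene regulatory module yields a hybrid network mixing undirected PPI
edges with directed regulation edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx

from .densitometry import ActivationProfile
from .regulon import RegulatoryModule

logger = logging.getLogger(__name__)

MAX_PATHS = 10_000

NODE_CLASSES = ("receptor", "signaling", "tf", "gene", "other-signaling", "other-tf")


@dataclass
class PathSet:
    """All minimal-length paths between one source/target pair."""

    source: str
    target: str
    paths: list[list[str]]
    length: int  # hop count; -1 when unreachable
    unreachable: bool = False
    truncated: bool = False


@dataclass
class HybridNetwork:
    """PPI edges (undirected) plus TF→gene regulation edges (directed)."""

    ppi: nx.Graph
    regulation: nx.DiGraph
    node_class: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.ppi.nodes) | set(self.regulation.nodes)

    def counts(self) -> dict:
        by_class: dict[str, int] = {}
        for n in self.nodes:
            cls = self.node_class.get(n, "other-signaling")
            by_class[cls] = by_class.get(cls, 0) + 1
        return {
            "n_nodes": len(self.nodes),
            "n_edges": self.ppi.number_of_edges() + self.regulation.number_of_edges(),
            "n_ppi_edges": self.ppi.number_of_edges(),
            "n_regulation_edges": self.regulation.number_of_edges(),
            "nodes_by_class": by_class,
        }


def select_targets(
    profiles: list[ActivationProfile], ortholog_map: dict[str, str]
) -> set[str]:
    """Human-ortholog IDs of the intermediates whose activation flag is set.

    Raises
    ------
    ValueError
        If an activated intermediate is missing from the ortholog map.
    """
    targets = set()
    for p in profiles:
        if not p.activated:
            continue
        if p.target not in ortholog_map:
            raise ValueError(
                f"activated intermediate {p.target!r} missing from ortholog map"
            )
        targets.add(ortholog_map[p.target])
    return targets


def all_shortest_paths(
    network: nx.Graph, source: str, target: str, max_paths: int = MAX_PATHS
) -> PathSet:
    """Enumerate every minimal-hop path from source to target.

    Breadth-first over unit-weight edges; enumeration is capped at
    ``max_paths`` with the truncation flag set, since the number of tied
    shortest paths can grow combinatorially.
    """
    for node, name in ((source, "source"), (target, "target")):
        if node not in network:
            raise ValueError(f"{name} node {node!r} not in network")
    try:
        paths = list(islice(nx.all_shortest_paths(network, source, target), max_paths + 1))
    except nx.NetworkXNoPath:
        logger.warning("target %s unreachable from %s", target, source)
        return PathSet(source, target, [], length=-1, unreachable=True)
    truncated = len(paths) > max_paths
    if truncated:
        logger.warning(
            "path enumeration %s->%s truncated at %d paths", source, target, max_paths
        )
        paths = paths[:max_paths]
    return PathSet(source, target, paths, length=len(paths[0]) - 1, truncated=truncated)


def merge_paths(path_sets: list[PathSet]) -> nx.Graph:
    """Union of all nodes and consecutive-pair edges across all paths."""
    merged = nx.Graph()
    for ps in path_sets:
        for path in ps.paths:
            merged.add_nodes_from(path)
            merged.add_edges_from(zip(path, path[1:]))
    return merged


def assemble_hybrid(
    stage1: nx.Graph,
    stage2: nx.Graph,
    dor: RegulatoryModule,
    classes: dict[str, str],
) -> HybridNetwork:
    """Merge the receptor→intermediate and intermediate→TF subnetworks with
    the TF→gene regulatory module.

    Nodes missing from ``classes`` default to other-signaling with a warning;
    DOR TFs absent from the PPI stages are added as tf-class nodes.  Gene
    nodes never receive PPI edges.
    """
    ppi = nx.Graph()
    ppi.add_nodes_from(stage1.nodes)
    ppi.add_nodes_from(stage2.nodes)
    ppi.add_edges_from(stage1.edges)
    ppi.add_edges_from(stage2.edges)

    regulation = nx.DiGraph()
    for tf, gene in sorted(dor.edges):
        regulation.add_edge(tf, gene)

    node_class = dict(classes)
    for tf in dor.tf_set:
        node_class.setdefault(tf, "tf")
    for gene in dor.gene_set:
        node_class.setdefault(gene, "gene")
    for n in set(ppi.nodes) | set(regulation.nodes):
        if n not in node_class:
            logger.warning("node %s missing from class map; defaulting to other-signaling", n)
            node_class[n] = "other-signaling"

    bad = [
        (t, g) for t, g in regulation.edges
        if node_class[t] not in ("tf", "other-tf") or node_class[g] != "gene"
    ]
    if bad:
        raise ValueError(f"regulation edges must run tf->gene; offending: {bad[:5]}")
    gene_ppi = [n for n in ppi.nodes if node_class.get(n) == "gene" and ppi.degree(n) > 0]
    if gene_ppi:
        raise ValueError(f"gene-class nodes carry PPI edges: {gene_ppi[:5]}")

    n_receptor = sum(1 for n, c in node_class.items()
                     if c == "receptor" and n in (set(ppi.nodes) | set(regulation.nodes)))
    if n_receptor > 1:
        raise ValueError("hybrid network must contain exactly one receptor node")
    return HybridNetwork(ppi=ppi, regulation=regulation, node_class=node_class)
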