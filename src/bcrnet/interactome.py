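"""Evidence-filtered protein–protein interactome construction.

Interaction records from several source databases (MITAB-like TSV: two
interactor IDs, pipe-separated publication IDs, source database) are merged
into one undirected network.  Edge evidence is the number of *distinct*
publications supporting the pair across all sources — databases heavily
co-cite, so two databases citing the same study count once.  Edges lacking
support from at least two independent studies are removed, isolated nodes
pruned, and receptor subunits (CD79A/CD79B) can be collapsed into a single
BCR complex node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

MIN_STUDIES = 2


@dataclass(frozen=True)
class InteractionRecord:
    """One evidence-annotated protein pair from one source database."""

    id_a: str
    id_b: str
    publications: frozenset[str]
    source_db: str

    def __post_init__(self) -> None:
        if not self.publications:
            raise ValueError(f"record {self.id_a}-{self.id_b} has no publications")


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Parse a MITAB-like TSV: id_a, id_b, pipe-separated publication IDs,
    source database.  Malformed rows are skipped with a logged line number.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If every row is malformed.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.split("\t")
            if len(fields) < 4:
                logger.warning("%s:%d: expected >=4 columns, skipped", path, lineno)
                continue
            id_a, id_b, pubs_field, source = fields[0], fields[1], fields[2], fields[3]
            pubs = frozenset(p for p in pubs_field.split("|") if p)
            if not id_a or not id_b or not pubs:
                logger.warning("%s:%d: empty interactor or publication field, skipped",
                               path, lineno)
                continue
            records.append(InteractionRecord(id_a, id_b, pubs, source))
    if n_rows and not records:
        raise ValueError(f"{path}: all {n_rows} rows malformed")
    return records


def map_orthologs(
    records: list[InteractionRecord], mapping: dict[str, str]
) -> list[InteractionRecord]:
    """Remap both interactors through an ortholog table (many-to-one allowed).

    Records with either side absent from the mapping are dropped; the drop
    count is logged.
    """
    if not mapping:
        raise ValueError("ortholog mapping is empty")
    mapped, dropped = [], 0
    for rec in records:
        if rec.id_a in mapping and rec.id_b in mapping:
            mapped.append(
                InteractionRecord(
                    mapping[rec.id_a], mapping[rec.id_b], rec.publications, rec.source_db
                )
            )
        else:
            dropped += 1
    if dropped:
        logger.info("map_orthologs: dropped %d records with unmapped interactors", dropped)
    return mapped


def merge_databases(record_tables: list[list[InteractionRecord]]) -> nx.Graph:
    """Merge record tables into one undirected network.

    One edge per unordered pair; ``evidence`` is the count of distinct
    publication IDs across all sources, ``sources`` the union of database
    names.  Self-interactions are dropped here.
    """
    graph = nx.Graph()
    for table in record_tables:
        for rec in table:
            if rec.id_a == rec.id_b:
                continue
            u, v = sorted((rec.id_a, rec.id_b))
            if graph.has_edge(u, v):
                data = graph.edges[u, v]
                data["publications"] |= rec.publications
                data["sources"].add(rec.source_db)
            else:
                graph.add_edge(
                    u, v,
                    publications=set(rec.publications),
                    sources={rec.source_db},
                )
    for _, _, data in graph.edges(data=True):
        data["evidence"] = len(data["publications"])
    return graph


def filter_min_evidence(network: nx.Graph, min_studies: int = MIN_STUDIES) -> nx.Graph:
    """Keep edges supported by at least ``min_studies`` distinct publications;
    prune nodes left isolated."""
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    filtered = nx.Graph()
    filtered.add_nodes_from(network.nodes(data=True))
    for u, v, data in network.edges(data=True):
        if data.get("evidence", len(data.get("publications", ()))) >= min_studies:
            filtered.add_edge(u, v, **{k: _copy_attr(x) for k, x in data.items()})
    filtered.remove_nodes_from([n for n in filtered if filtered.degree(n) == 0])
    return filtered


def _copy_attr(value):
    return set(value) if isinstance(value, set) else value


def collapse_complex(network: nx.Graph, members: set[str], label: str) -> nx.Graph:
    """Replace ``members`` by a single complex node carrying the union of
    their edges.

    Edges internal to the complex are removed.  Where several member edges
    point at the same partner, the merged edge keeps the *maximum* evidence
    of the merged edges (a publication reported for two subunits is one
    study, not two) and the union of publications and sources.
    """
    missing = set(members) - set(network.nodes)
    if missing:
        raise ValueError(f"complex members not in network: {sorted(missing)}")
    collapsed = nx.Graph()
    for n, data in network.nodes(data=True):
        if n not in members:
            collapsed.add_node(n, **data)
    collapsed.add_node(label)
    for u, v, data in network.edges(data=True):
        u2 = label if u in members else u
        v2 = label if v in members else v
        if u2 == v2:
            continue
        attrs = {k: _copy_attr(x) for k, x in data.items()}
        if collapsed.has_edge(u2, v2):
            existing = collapsed.edges[u2, v2]
            existing["evidence"] = max(existing["evidence"], attrs.get("evidence", 1))
            existing["publications"] |= attrs.get("publications", set())
            existing["sources"] |= attrs.get("sources", set())
        else:
            attrs.setdefault("publications", set())
            attrs.setdefault("sources", set())
            attrs.setdefault("evidence", len(attrs["publications"]) or 1)
            collapsed.add_edge(u2, v2, **attrs)
    return collapsed


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV: id_a, id_b, evidence, sources (pipe-separated)."""
    with Path(path).open("w") as fh:
        fh.write("id_a\tid_b\tevidence\tsources\n")
        for u, v, data in sorted(network.edges(data=True)):
            sources = "|".join(sorted(data.get("sources", ())))
            fh.write(f"{u}\t{v}\t{data.get('evidence', 1)}\t{sources}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    graph = nx.Graph()
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("id_a"):
            raise ValueError(f"{path}: missing edge-list header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            u, v, evidence = fields[0], fields[1], int(fields[2])
            sources = set(fields[3].split("|")) if len(fields) > 3 and fields[3] else set()
            graph.add_edge(u, v, evidence=evidence, sources=sources, publications=set())
    return graph


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    # GraphML cannot serialize sets; flatten them
    export = nx.Graph()
    export.add_nodes_from(network.nodes)
    for u, v, data in network.edges(data=True):
        export.add_edge(
            u, v,
            evidence=int(data.get("evidence", 1)),
            sources="|".join(sorted(data.get("sources", ()))),
            publications="|".join(sorted(data.get("publications", ()))),
        )
    nx.write_graphml(export, str(path))
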