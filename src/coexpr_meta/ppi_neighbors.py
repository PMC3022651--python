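"""First-neighbor subnetwork extraction from a protein-interaction graph.

Consumes a pre-built interaction edge list (SIF or two-column TSV) as an
undirected simple graph over uppercased gene symbols. Around a list of
seed genes the *induced* first-neighbor subgraph is taken — mapped seeds
plus all their neighbors, keeping every original edge between retained
nodes (neighbor-neighbor edges included). A tissue-expression filter
then drops nodes whose expression is not strictly above a threshold
(nodes with unknown expression fail the filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from coexpr_meta.errors import ValidationError

logger = logging.getLogger(__name__)


def read_edge_list(path, format: str = "SIF") -> nx.Graph:
    """Read an interaction graph from SIF or two-column TSV.

    SIF lines are ``source relation target [target...]`` (the relation
    type is ignored); a line with a single token declares an isolated
    node. Symbols are uppercased, self-loops dropped (count logged),
    duplicate edges collapsed.
    """
    fmt = format.upper()
    if fmt not in ("SIF", "TSV"):
        raise ValidationError(f"unknown edge-list format {format!r}")
    graph = nx.Graph()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p for p in line.replace("\t", " ").split(" ") if p]
            if fmt == "SIF":
                if len(parts) == 1:
                    graph.add_node(parts[0].upper())
                    continue
                if len(parts) == 2:
                    raise ValidationError(
                        f"line {lineno}: SIF needs source, relation and "
                        f">= 1 target"
                    )
                src = parts[0].upper()
                targets = [p.upper() for p in parts[2:]]
            else:
                if len(parts) != 2:
                    raise ValidationError(
                        f"line {lineno}: TSV edge list needs exactly 2 columns, "
                        f"found {len(parts)}"
                    )
                src = parts[0].upper()
                targets = [parts[1].upper()]
            for tgt in targets:
                if src == tgt:
                    self_loops += 1
                    continue
                graph.add_edge(src, tgt)
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    return graph


def first_neighbor_subgraph(graph: nx.Graph, seeds) -> tuple[nx.Graph, int]:
    """Induced subgraph on mapped seeds and their first neighbors.

    Seeds absent from the graph are counted as unmapped. Returns the
    subgraph (a copy) and the number of mapped seeds.
    """
    mapped = [s.upper() for s in seeds if s.upper() in graph]
    keep = set(mapped)
    for s in mapped:
        keep.update(graph.neighbors(s))
    return graph.subgraph(keep).copy(), len(mapped)


def expression_filter(
    graph: nx.Graph, expr: dict[str, float], threshold: float = 200.0
) -> nx.Graph:
    """Induced subgraph on nodes with expression strictly above ``threshold``.

    Nodes missing from ``expr`` are dropped (unknown expression fails).
    """
    expr = {k.upper(): v for k, v in expr.items()}
    keep = [n for n in graph if n in expr and expr[n] > threshold]
    return graph.subgraph(keep).copy()


@dataclass(frozen=True)
class SubgraphStats:
    node_count: int
    edge_count: int
    neighbor_counts: dict[str, int]  # per-seed degree within the graph


def subgraph_stats(graph: nx.Graph, seeds=None) -> SubgraphStats:
    """Node/edge counts and, when seeds are given, per-seed neighbor counts."""
    counts: dict[str, int] = {}
    for s in sorted(s.upper() for s in (seeds or ())):
        counts[s] = graph.degree(s) if s in graph else 0
    return SubgraphStats(
        node_count=graph.number_of_nodes(),
        edge_count=graph.number_of_edges(),
        neighbor_counts=counts,
    )


def write_node_table(graph: nx.Graph, path, expr: dict[str, float] | None = None) -> None:
    expr = {k.upper(): v for k, v in (expr or {}).items()}
    with open(path, "w") as fh:
        fh.write("node\tdegree\texpression\n")
        for node in sorted(graph):
            e = expr.get(node)
            fh.write(f"{node}\t{graph.degree(node)}\t{'' if e is None else e}\n")


def write_edge_table(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")
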