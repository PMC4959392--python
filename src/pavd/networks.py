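"""Pathway network assembly and candidate-family enumeration.

A pathway's *normal* network is built by taking its gene set, keeping the
genes observed in the expression data, and connecting them with every
catalog interaction whose endpoints both survive.  Because the scoring
engine models a network as a discrete Bayesian network, the result must be
a simple DAG; the conventions for getting there (edge orientation,
anti-parallel collapse, cycle breaking) are deterministic and documented on
:func:`assemble_network`.

Disturbance of a pathway is modeled as *silencing* single interactions: the
candidate family of a pathway with E edges has N = E + 1 members — the
normal network plus one variant per deleted edge, in lexicographic edge
order, with the normal network always at index 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx

from .io import BinaryExpressionMatrix, GeneSet, InteractionCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayNetwork",
    "CandidateNetworkFamily",
    "UnusablePathwayError",
    "DIRECTED_RELATIONS",
    "assemble_network",
    "enumerate_candidates",
    "build_families",
    "families_to_json",
    "families_from_json",
]

# Pathway Commons SIF relation types that carry a source -> target direction.
# Any other label (interacts-with, in-complex-with, ...) is undirected and
# gets the lexicographic orientation.
DIRECTED_RELATIONS = frozenset({
    "controls-state-change-of",
    "controls-transport-of",
    "controls-phosphorylation-of",
    "controls-expression-of",
    "controls-production-of",
    "controls-transport-of-chemical",
    "catalysis-precedes",
    "consumption-controlled-by",
    "chemical-affects",
    "used-to-produce",
})

Edge = tuple[str, str]


@dataclass(frozen=True)
class PathwayNetwork:
    """A simple DAG over a pathway's observed genes.

    ``edges`` are kept sorted lexicographically, so equal networks compare
    equal and iteration order is reproducible.
    """

    pathway_id: str
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError(f"{self.pathway_id}: duplicate nodes")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"{self.pathway_id}: self-loop {u}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"{self.pathway_id}: edge ({u}, {v}) endpoint not a node")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError(f"{self.pathway_id}: parallel edges")
        object.__setattr__(self, "edges", tuple(sorted(self.edges)))
        graph = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError(f"{self.pathway_id}: network contains a cycle")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def without_edge(self, edge: Edge) -> "PathwayNetwork":
        if edge not in self.edges:
            raise ValueError(f"{self.pathway_id}: no edge {edge}")
        return PathwayNetwork(
            self.pathway_id, self.nodes, tuple(e for e in self.edges if e != edge)
        )

    def topological_order(self) -> list[str]:
        graph = nx.DiGraph(self.edges)
        graph.add_nodes_from(self.nodes)
        return list(nx.lexicographical_topological_sort(graph))


class UnusablePathwayError(ValueError):
    """Raised for pathways that cannot form a candidate family (no edges)."""


@dataclass(frozen=True)
class CandidateNetworkFamily:
    """Normal network plus all single-edge-silenced variants (N = E + 1)."""

    pathway_id: str
    normal: PathwayNetwork
    variants: tuple[tuple[Edge, PathwayNetwork], ...]

    @property
    def n_candidates(self) -> int:
        return 1 + len(self.variants)

    @property
    def candidate_labels(self) -> tuple[str, ...]:
        return ("Normal",) + tuple(f"{u}->{v}" for (u, v), _ in self.variants)

    def networks(self) -> list[PathwayNetwork]:
        return [self.normal] + [net for _, net in self.variants]


def assemble_network(
    gene_set: GeneSet,
    catalog: InteractionCatalog,
    available_genes: set[str],
) -> PathwayNetwork:
    """Build a pathway's normal network from its gene set and the catalog.

    Conventions (all deterministic):

    * nodes = gene-set members present in ``available_genes``, in gene-set
      order;
    * a catalog interaction contributes an edge when both endpoints are
      nodes; its direction is kept if the relation label is one of
      :data:`DIRECTED_RELATIONS`, otherwise the pair is oriented
      lexicographically smaller -> larger;
    * if both orientations of a pair survive, only the lexicographic one is
      kept;
    * remaining cycles are broken by depth-first search started from
      lexicographically sorted nodes (neighbors visited in sorted order),
      removing back edges in discovery order.

    Removed edges are reported through the module logger.
    """
    nodes = tuple(g for g in gene_set.genes if g in available_genes)
    node_set = set(nodes)
    directed: set[Edge] = set()
    for source, target, relation in catalog:
        if source not in node_set or target not in node_set:
            continue
        if relation in DIRECTED_RELATIONS:
            directed.add((source, target))
        else:
            directed.add((min(source, target), max(source, target)))
    # anti-parallel collapse: keep only the lexicographic orientation
    dropped_antiparallel = {(u, v) for (u, v) in directed if (v, u) in directed and u > v}
    edges = directed - dropped_antiparallel
    if dropped_antiparallel:
        logger.info("%s: collapsed %d anti-parallel edges",
                    gene_set.set_id, len(dropped_antiparallel))
    acyclic = _remove_back_edges(nodes, edges, gene_set.set_id)
    return PathwayNetwork(gene_set.set_id, nodes, tuple(sorted(acyclic)))


def _remove_back_edges(nodes: tuple[str, ...], edges: set[Edge], pathway_id: str) -> set[Edge]:
    """Iterative DFS from sorted roots; back edges removed in discovery order."""
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in sorted(edges):
        succ[u].append(v)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}
    removed: set[Edge] = set()
    for root in sorted(nodes):
        if color[root] != WHITE:
            continue
        # stack of (node, iterator position over its sorted successors)
        stack: list[tuple[str, int]] = [(root, 0)]
        color[root] = GRAY
        while stack:
            node, pos = stack[-1]
            if pos < len(succ[node]):
                stack[-1] = (node, pos + 1)
                child = succ[node][pos]
                if (node, child) in removed:
                    continue
                if color[child] == GRAY:  # back edge: closes a cycle
                    removed.add((node, child))
                elif color[child] == WHITE:
                    color[child] = GRAY
                    stack.append((child, 0))
            else:
                color[node] = BLACK
                stack.pop()
    if removed:
        logger.info("%s: removed %d cycle-closing edges: %s",
                    pathway_id, len(removed), sorted(removed))
    return edges - removed


def enumerate_candidates(network: PathwayNetwork) -> CandidateNetworkFamily:
    """Enumerate the candidate family: normal + one variant per deleted edge."""
    if network.n_edges == 0:
        raise UnusablePathwayError(
            f"pathway {network.pathway_id!r} has no edges; no candidate family"
        )
    variants = tuple(
        (edge, network.without_edge(edge)) for edge in network.edges  # edges are sorted
    )
    return CandidateNetworkFamily(network.pathway_id, network, variants)


def build_families(
    gene_sets: list[GeneSet],
    catalog: InteractionCatalog,
    binary_matrix: BinaryExpressionMatrix,
    min_edges: int = 1,
) -> list[CandidateNetworkFamily]:
    """Assemble and enumerate one family per usable gene set.

    Gene sets whose assembled network has fewer than ``min_edges`` edges are
    skipped (counted in the log); input order is preserved.
    """
    if min_edges < 1:
        raise ValueError("min_edges must be >= 1")
    available = set(binary_matrix.gene_ids)
    families: list[CandidateNetworkFamily] = []
    n_skipped = 0
    for gene_set in gene_sets:
        network = assemble_network(gene_set, catalog, available)
        if network.n_edges < min_edges:
            n_skipped += 1
            logger.info("skipping %s: %d edges < min_edges=%d",
                        gene_set.set_id, network.n_edges, min_edges)
            continue
        families.append(enumerate_candidates(network))
    if not families:
        logger.warning("no usable pathways (all %d gene sets below min_edges)", n_skipped)
    return families


def families_to_json(families: list[CandidateNetworkFamily], path) -> None:
    payload = [
        {
            "pathway_id": fam.pathway_id,
            "nodes": list(fam.normal.nodes),
            "edges": [list(e) for e in fam.normal.edges],
        }
        for fam in families
    ]
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)
        handle.write("\n")


def families_from_json(path) -> list[CandidateNetworkFamily]:
    with open(path) as handle:
        payload = json.load(handle)
    families = []
    for rec in payload:
        network = PathwayNetwork(
            rec["pathway_id"],
            tuple(rec["nodes"]),
            tuple((u, v) for u, v in rec["edges"]),
        )
        families.append(enumerate_candidates(network))
    return families
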