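"""The global typed graph over all genes and proteins in a datastore.

One supergraph is assembled per store and is read-only afterwards; every
query network is cut out of it.  Genes connect to their protein products
through coding edges, proteins connect to interaction partners through PPI
edges, and proteins connect to the genes they regulate through protein–DNA
edges.  Coding edges have length 0 and all others length 1, so a gene and
its products sit at the same distance from any seed set.

Directed relation types (coding, pdna) keep their stored direction as an
edge attribute but are traversable in both directions during expansion:
building outward from a gene must cross its gene→protein coding edge from
the gene side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .datastore import (
    CODING,
    DataStore,
    DataStoreError,
    EvidenceEdge,
    PDNA,
    PPI,
    REL_TYPES,
)

__all__ = ["EDGE_LENGTH", "EdgeFilter", "SuperGraph", "assemble_supergraph"]

#: weighted length of an edge by relation type (coding relations are free)
EDGE_LENGTH = {CODING: 0, PPI: 1, PDNA: 1}


@dataclass(frozen=True)
class EdgeFilter:
    """Evidence-aware edge selection.

    An empty ``sources``/``methods`` set means "no restriction".  An edge
    survives the filter when its relation type is allowed and at least one
    of its evidence items passes both the source and the method restriction
    (any-evidence semantics: an edge with mixed provenance is kept as long
    as one supporting observation qualifies).
    """

    sources: frozenset[str] = frozenset()
    methods: frozenset[str] = frozenset()
    rel_types: frozenset[str] = frozenset(REL_TYPES)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "methods", frozenset(self.methods))
        object.__setattr__(self, "rel_types", frozenset(self.rel_types))
        if not self.rel_types:
            raise ValueError("EdgeFilter.rel_types must be non-empty")
        unknown = self.rel_types - set(REL_TYPES)
        if unknown:
            raise ValueError(f"unknown rel_types in filter: {sorted(unknown)}")

    def admits(self, edge: EvidenceEdge) -> bool:
        if edge.rel_type not in self.rel_types:
            return False
        return any(
            (not self.sources or ev.source_db in self.sources)
            and (not self.methods or ev.method in self.methods)
            for ev in edge.evidence
        )


class SuperGraph:
    """Immutable-by-convention multigraph over every entity in the store."""

    def __init__(self, store: DataStore) -> None:
        g = nx.MultiGraph()
        for iid, ent in store.entities.items():
            g.add_node(iid, entity=ent)
        for edge in store.edges:
            g.add_edge(edge.a, edge.b, key=edge.edge_id, edge=edge)
        self._g = g
        self._store = store
        self._edges = {e.edge_id: e for e in store.edges}

    @property
    def nx_graph(self) -> nx.MultiGraph:
        return self._g

    @property
    def store(self) -> DataStore:
        return self._store

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def entity(self, node: str):
        return self._store.entity(node)

    def edge(self, edge_id: str) -> EvidenceEdge:
        return self._edges[edge_id]

    def neighbors(self, node: str, f: EdgeFilter) -> list[tuple[str, EvidenceEdge]]:
        """Filter-surviving incident edges, sorted by (neighbor, edge_id).

        A self-interaction contributes one entry with the node itself as
        the neighbor.
        """
        if node not in self._g:
            raise DataStoreError(f"unknown node {node!r}")
        out = []
        for nbr, keyed in self._g.adj[node].items():
            for edge_id, attrs in keyed.items():
                edge: EvidenceEdge = attrs["edge"]
                if f.admits(edge):
                    out.append((nbr, edge))
        out.sort(key=lambda pair: (pair[0], pair[1].edge_id))
        return out

    def coding_partners(self, node: str) -> list[str]:
        """Products of a gene, or coding genes of a protein (unfiltered)."""
        partners = []
        for nbr, keyed in self._g.adj[node].items():
            for attrs in keyed.values():
                if attrs["edge"].rel_type == CODING:
                    partners.append(nbr)
        return sorted(set(partners))


def assemble_supergraph(store: DataStore) -> SuperGraph:
    """Build the supergraph; node count equals entity count, edge multiset
    equals the store's merged edge list.  Idempotent for a given store."""
    return SuperGraph(store)
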