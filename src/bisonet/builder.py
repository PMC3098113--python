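"""Seed-based network construction.

Building a network is a three-step pipeline:

1. **identify** — each input token is mapped through the translation table
   to supergraph nodes (the seed set), restricted to the query's organism
   and entity kinds;
2. **expand** — the seed set is grown to every node within weighted
   distance N, where coding edges cost 0 and interaction edges cost 1
   (multi-source 0-1 BFS over filter-surviving edges), and the induced
   subgraph on that node set is taken, which interconnects the seeds;
3. **project** — the mixed gene/protein subgraph is rendered as genes
   only, proteins only, or both with explicit coding relations.

Unresolvable input tokens are reported, never fatal; only an entirely
empty seed set aborts a build.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .datastore import (
    CODING,
    DataStore,
    Evidence,
    EvidenceEdge,
    GENE,
    PDNA,
    PPI,
    PROTEIN,
    TranslationTable,
    build_translation_table,
)
from .supergraph import EDGE_LENGTH, EdgeFilter, SuperGraph, assemble_supergraph

__all__ = [
    "GENES_ONLY",
    "PROTEINS_ONLY",
    "GENES_AND_PROTEINS",
    "OUTPUT_MODES",
    "IMPORTED",
    "EXTERNAL",
    "NetworkQuery",
    "BuiltNetwork",
    "Subgraph",
    "BuildError",
    "identify_seeds",
    "expand",
    "project",
    "build_network",
    "expand_network",
    "convert_network",
    "parse_external_edges",
]

GENES_ONLY = "genes_only"
PROTEINS_ONLY = "proteins_only"
GENES_AND_PROTEINS = "genes_and_proteins_with_coding"
OUTPUT_MODES = (GENES_ONLY, PROTEINS_ONLY, GENES_AND_PROTEINS)

#: relation type assigned to external edges with no datastore counterpart
IMPORTED = "imported"
#: node kind for unresolved external node names kept during conversion
EXTERNAL = "external"


class BuildError(ValueError):
    """Raised when a network cannot be built from the given inputs."""


@dataclass(frozen=True)
class NetworkQuery:
    """Everything a network-construction request specifies.

    ``distance`` is the inclusion radius N: the result contains every node
    within weighted shortest distance N of the seed set.  N = 0 still pulls
    in the products of seed genes when coding edges pass the filter,
    because coding relations have length zero.
    """

    organism: int
    identify_kinds: frozenset[str] = frozenset({GENE, PROTEIN})
    filter: EdgeFilter = field(default_factory=EdgeFilter)
    distance: int = 1
    output_mode: str = GENES_AND_PROTEINS

    def __post_init__(self) -> None:
        object.__setattr__(self, "identify_kinds", frozenset(self.identify_kinds))
        if not self.identify_kinds:
            raise BuildError("identify_kinds must be non-empty")
        if self.identify_kinds - {GENE, PROTEIN}:
            raise BuildError(f"unknown identify_kinds {sorted(self.identify_kinds)}")
        if self.distance < 0:
            raise BuildError("distance must be >= 0")
        if self.output_mode not in OUTPUT_MODES:
            raise BuildError(f"unknown output mode {self.output_mode!r}")


@dataclass
class Subgraph:
    """Expansion result prior to projection: distances plus induced edges."""

    graph: SuperGraph
    seeds: frozenset[str]
    distances: dict[str, int]
    edges: list[EvidenceEdge]
    filter: EdgeFilter


@dataclass
class BuiltNetwork:
    """A constructed network: an attributed multigraph plus its provenance.

    Node attributes: ``kind``, ``label``, ``description``, ``go_terms``,
    ``pathways``, ``is_seed``, ``distance``.  Edge attributes (keyed by
    edge id): ``rel_type``, ``src``, ``dst`` (stored direction), ``evidence``,
    ``dashed`` (render hint for coding relations).
    """

    graph: nx.MultiGraph
    query: NetworkQuery | None = None
    unresolved_tokens: list[tuple[str, str]] = field(default_factory=list)
    conversion_stats: dict[str, int] | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def node_attrs(self, node: str) -> dict:
        return self.graph.nodes[node]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def labels(self) -> dict[str, str]:
        return {n: d["label"] for n, d in self.graph.nodes(data=True)}

    def seeds(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["is_seed"]}

    def simple_graph(self, *, drop_loops: bool = False) -> nx.Graph:
        """Collapse parallel edges; optionally drop self-loops."""
        s = nx.Graph()
        s.add_nodes_from(self.graph.nodes)
        for u, v in self.graph.edges():
            if drop_loops and u == v:
                continue
            s.add_edge(u, v)
        return s

    def equals(self, other: "BuiltNetwork") -> bool:
        """Structural equality of nodes, edges and all their attributes."""
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            if dict(self.graph.nodes[n]) != dict(other.graph.nodes[n]):
                return False
        mine = {k: d for _, _, k, d in self.graph.edges(keys=True, data=True)}
        theirs = {k: d for _, _, k, d in other.graph.edges(keys=True, data=True)}
        if mine.keys() != theirs.keys():
            return False
        for k in mine:
            if mine[k] != theirs[k]:
                return False
        return (
            self.query == other.query
            and sorted(self.unresolved_tokens) == sorted(other.unresolved_tokens)
        )


# ---------------------------------------------------------------------------
# step 1: identify


def identify_seeds(
    tokens: Sequence[str],
    q: NetworkQuery,
    table: TranslationTable,
    g: SuperGraph,
) -> tuple[frozenset[str], list[tuple[str, str]]]:
    """Map input tokens to seed nodes; report tokens contributing none."""
    if not tokens:
        raise BuildError("no input identifiers")
    seeds: set[str] = set()
    report: list[tuple[str, str]] = []
    for token in tokens:
        res = table.resolve(token, q.organism, q.identify_kinds)
        hits = {i for i in res.ids if i in g}
        if hits:
            seeds.update(hits)
        else:
            report.append((token, res.status if res.status != "resolved" else "unresolved"))
    return frozenset(seeds), report


# ---------------------------------------------------------------------------
# step 2: expand


def expand(g: SuperGraph, seeds: Iterable[str], f: EdgeFilter, n: int) -> Subgraph:
    """Grow the seed set to all nodes within weighted distance ``n``.

    Distances are multi-source shortest path lengths where coding edges
    have length 0 and everything else length 1, computed with a 0-1 BFS
    (deque: zero-length edges are relaxed at the front).  The edge set is
    the *induced* one — every filter-surviving supergraph edge with both
    endpoints inside the node set — so seeds already adjacent in the
    supergraph come out interconnected.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise BuildError("expand requires a non-empty seed set")
    missing = [s for s in seeds if s not in g]
    if missing:
        raise BuildError(f"seed nodes not in supergraph: {sorted(missing)}")
    if n < 0:
        raise BuildError("distance must be >= 0")

    dist: dict[str, int] = {s: 0 for s in seeds}
    dq: deque[str] = deque(sorted(seeds))
    while dq:
        node = dq.popleft()
        d = dist[node]
        for nbr, edge in g.neighbors(node, f):
            nd = d + EDGE_LENGTH[edge.rel_type]
            if nd <= n and nd < dist.get(nbr, n + 1):
                dist[nbr] = nd
                if EDGE_LENGTH[edge.rel_type] == 0:
                    dq.appendleft(nbr)
                else:
                    dq.append(nbr)

    included = set(dist)
    edges: dict[str, EvidenceEdge] = {}
    for node in included:
        for _, edge in g.neighbors(node, f):
            if edge.a in included and edge.b in included:
                edges[edge.edge_id] = edge
    return Subgraph(
        graph=g,
        seeds=seeds,
        distances=dist,
        edges=[edges[k] for k in sorted(edges)],
        filter=f,
    )


# ---------------------------------------------------------------------------
# step 3: project


def _node_payload(g: SuperGraph, node: str, is_seed: bool, distance: int) -> dict:
    ent = g.entity(node)
    return {
        "kind": ent.kind,
        "label": ent.primary_label,
        "description": ent.description,
        "go_terms": ent.go_terms,
        "pathways": ent.pathways,
        "is_seed": is_seed,
        "distance": distance,
    }


def _merge_evidence(*groups: tuple[Evidence, ...]) -> tuple[Evidence, ...]:
    seen = set()
    for grp in groups:
        seen.update(grp)
    return tuple(sorted(seen, key=lambda e: (e.source_db, e.method, e.pubmed_ids)))


def _passthrough(sub: Subgraph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for node, d in sub.distances.items():
        g.add_node(node, **_node_payload(sub.graph, node, node in sub.seeds, d))
    for edge in sub.edges:
        g.add_edge(
            edge.a,
            edge.b,
            key=edge.edge_id,
            rel_type=edge.rel_type,
            src=edge.a,
            dst=edge.b,
            evidence=edge.evidence,
            dashed=edge.rel_type == CODING,
        )
    return g


def _coding_genes(sub: Subgraph, protein: str) -> list[str]:
    # projection maps a protein onto its coding gene(s) from the full store
    # relation, independent of the query's edge filter: projection is a
    # change of representation, not an interaction selection
    return [
        p for p in sub.graph.coding_partners(protein)
        if sub.graph.entity(p).kind == GENE
    ]


def _genes_only(sub: Subgraph) -> nx.MultiGraph:
    import warnings

    g = nx.MultiGraph()
    sg = sub.graph
    gene_seed: dict[str, bool] = {}
    gene_dist: dict[str, int] = {}

    genes_of: dict[str, list[str]] = {}
    for node, d in sub.distances.items():
        ent = sg.entity(node)
        if ent.kind == GENE:
            gene_dist[node] = min(gene_dist.get(node, d), d)
            gene_seed[node] = gene_seed.get(node, False) or node in sub.seeds
        else:
            coders = _coding_genes(sub, node)
            if not coders:
                warnings.warn(
                    f"protein {node!r} has no coding gene in the store; dropped "
                    f"from gene-level projection",
                    stacklevel=3,
                )
                continue
            genes_of[node] = coders
            for gene in coders:
                gene_dist[gene] = min(gene_dist.get(gene, d), d)
                gene_seed[gene] = gene_seed.get(gene, False) or node in sub.seeds

    for gene in sorted(gene_dist):
        g.add_node(gene, **_node_payload(sg, gene, gene_seed[gene], gene_dist[gene]))

    # contract edges; parallel projected edges merge, within-gene self edges drop
    acc: dict[tuple[str, str, str], tuple[Evidence, ...]] = {}
    for edge in sub.edges:
        if edge.rel_type == CODING:
            continue
        if edge.rel_type == PPI:
            pairs = [
                (ga, gb)
                for ga in genes_of.get(edge.a, [])
                for gb in genes_of.get(edge.b, [])
                if ga != gb
            ]
            for ga, gb in pairs:
                u, v = sorted((ga, gb))
                key = (PPI, u, v)
                acc[key] = _merge_evidence(acc.get(key, ()), edge.evidence)
        elif edge.rel_type == PDNA:
            for gp in genes_of.get(edge.a, []):
                if gp == edge.b or edge.b not in gene_dist:
                    continue
                key = (PDNA, gp, edge.b)
                acc[key] = _merge_evidence(acc.get(key, ()), edge.evidence)
    for (rel, u, v), evidence in sorted(acc.items()):
        g.add_edge(
            u, v,
            key=f"{rel}:{u}--{v}",
            rel_type=rel,
            src=u,
            dst=v,
            evidence=evidence,
            dashed=False,
        )
    return g


def _proteins_only(sub: Subgraph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    sg = sub.graph
    proteins = {
        node: d for node, d in sub.distances.items() if sg.entity(node).kind == PROTEIN
    }
    seed_genes = {s for s in sub.seeds if sg.entity(s).kind == GENE}
    for node in sorted(proteins):
        # a protein counts as seed if it was one, or if a seed gene codes it
        is_seed = node in sub.seeds or any(
            gene in seed_genes for gene in _coding_genes(sub, node)
        )
        g.add_node(node, **_node_payload(sg, node, is_seed, proteins[node]))

    acc: dict[tuple[str, str, str], tuple[Evidence, ...]] = {}
    keep: dict[str, EvidenceEdge] = {}
    for edge in sub.edges:
        if edge.rel_type == PPI:
            keep[edge.edge_id] = edge
        elif edge.rel_type == PDNA:
            # re-attach protein->gene regulation to the gene's products
            for product in sg.coding_partners(edge.b):
                if product in proteins and product != edge.a:
                    key = (PDNA, edge.a, product)
                    acc[key] = _merge_evidence(acc.get(key, ()), edge.evidence)
    for eid in sorted(keep):
        edge = keep[eid]
        g.add_edge(
            edge.a, edge.b, key=eid,
            rel_type=PPI, src=edge.a, dst=edge.b,
            evidence=edge.evidence, dashed=False,
        )
    for (rel, u, v), evidence in sorted(acc.items()):
        g.add_edge(
            u, v, key=f"{rel}:{u}->{v}",
            rel_type=rel, src=u, dst=v,
            evidence=evidence, dashed=False,
        )
    return g


def project(sub: Subgraph, mode: str, q: NetworkQuery | None = None) -> BuiltNetwork:
    """Render an expansion result in the requested representation."""
    if mode == GENES_AND_PROTEINS:
        graph = _passthrough(sub)
    elif mode == GENES_ONLY:
        graph = _genes_only(sub)
    elif mode == PROTEINS_ONLY:
        graph = _proteins_only(sub)
    else:
        raise BuildError(f"unknown output mode {mode!r}")
    return BuiltNetwork(graph=graph, query=q)


# ---------------------------------------------------------------------------
# composed operations


def build_network(
    tokens: Sequence[str],
    q: NetworkQuery,
    store: DataStore | None = None,
    *,
    graph: SuperGraph | None = None,
    table: TranslationTable | None = None,
) -> BuiltNetwork:
    """identify → expand → project, with the token report attached."""
    graph, table = _artifacts(store, graph, table)
    seeds, report = identify_seeds(tokens, q, table, graph)
    if not seeds:
        raise BuildError("no seeds identified")
    sub = expand(graph, seeds, q.filter, q.distance)
    net = project(sub, q.output_mode, q)
    net.unresolved_tokens = report
    return net


def _artifacts(
    store: DataStore | None,
    graph: SuperGraph | None,
    table: TranslationTable | None,
) -> tuple[SuperGraph, TranslationTable]:
    if graph is None:
        if store is None:
            raise BuildError("need a DataStore or a pre-built SuperGraph")
        graph = assemble_supergraph(store)
    if table is None:
        st = store if store is not None else graph.store
        table = build_translation_table(st.identifiers, st.entities)
    return graph, table


def expand_network(
    net: BuiltNetwork,
    selected: Iterable[str],
    q: NetworkQuery,
    g: SuperGraph,
) -> BuiltNetwork:
    """Grow an existing network outward from a selected node subset.

    The selected nodes (which are supergraph ids in every output mode) are
    re-expanded with the query's filter and distance; the result, projected
    in the existing network's mode, is unioned in.  Existing attributes are
    preserved; distances become the minimum of old and new, and seed flags
    accumulate.
    """
    selected = sorted(set(selected))
    if not selected:
        raise BuildError("no nodes selected for expansion")
    unknown = [s for s in selected if s not in net.graph]
    if unknown:
        raise BuildError(f"selected nodes not in network: {unknown}")
    mode = net.query.output_mode if net.query is not None else q.output_mode
    sub = expand(g, selected, q.filter, q.distance)
    addition = project(sub, mode, q)

    merged = net.graph.copy()
    for node, attrs in addition.graph.nodes(data=True):
        if node in merged:
            old = merged.nodes[node]
            old["distance"] = min(old["distance"], attrs["distance"])
            old["is_seed"] = old["is_seed"] or attrs["is_seed"]
        else:
            merged.add_node(node, **attrs)
    for u, v, key, attrs in addition.graph.edges(keys=True, data=True):
        if not merged.has_edge(u, v, key):
            merged.add_edge(u, v, key=key, **attrs)
    return BuiltNetwork(
        graph=merged,
        query=replace(q, output_mode=mode),
        unresolved_tokens=list(net.unresolved_tokens),
    )


# ---------------------------------------------------------------------------
# conversion of external networks


def parse_external_edges(
    source: str | Path | Iterable[str],
) -> tuple[list[str], list[tuple[str, str, str | None]]]:
    """Parse a SIF or 2-column edge list into node names and edges.

    Lines hold either a single node name, two tab-separated names (plain
    edge list) or the SIF form ``source<TAB>interaction<TAB>target...``.
    Returns ``(lone_nodes, [(a, b, interaction-or-None), ...])``.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            lines = path.read_text(encoding="utf-8").splitlines()
        except OSError as exc:
            raise BuildError(f"cannot read {path}: {exc}") from None
        origin = str(path)
    else:
        lines = list(source)
        origin = "<edges>"

    lone: list[str] = []
    edges: list[tuple[str, str, str | None]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if any(not f.strip() for f in fields):
            raise BuildError(f"{origin}:{lineno}: empty field in edge line")
        fields = [f.strip() for f in fields]
        if len(fields) == 1:
            lone.append(fields[0])
        elif len(fields) == 2:
            edges.append((fields[0], fields[1], None))
        else:
            a, interaction, *targets = fields
            for b in targets:
                edges.append((a, b, interaction))
    return lone, edges


def convert_network(
    source: str | Path | Iterable[str],
    q: NetworkQuery,
    store: DataStore | None = None,
    *,
    graph: SuperGraph | None = None,
    table: TranslationTable | None = None,
) -> BuiltNetwork:
    """Adopt an externally built network into the annotated representation.

    Each external node name is resolved through the translation table;
    resolved nodes receive full entity annotation, unresolved names stay in
    the network flagged as external so nothing silently disappears.  An
    external edge whose endpoints match a store relation inherits that
    relation's type and evidence; otherwise it is kept as an evidence-less
    ``imported`` edge.
    """
    graph, table = _artifacts(store, graph, table)
    lone, raw_edges = parse_external_edges(source)

    names: list[str] = []
    for name in lone:
        if name not in names:
            names.append(name)
    for a, b, _ in raw_edges:
        for name in (a, b):
            if name not in names:
                names.append(name)

    mapping: dict[str, str] = {}
    report: list[tuple[str, str]] = []
    stats = {"resolved": 0, "unresolved": 0, "discarded": 0}
    g = nx.MultiGraph()
    for name in names:
        res = table.resolve(name, q.organism, q.identify_kinds)
        if res.ids:
            # deterministic choice if a token names both a gene and a protein
            node = min(res.ids)
            mapping[name] = node
            stats["resolved"] += 1
            if node not in g:
                g.add_node(node, **_node_payload(graph, node, False, 0))
        else:
            mapping[name] = name
            stats[res.status] += 1
            report.append((name, res.status))
            if name not in g:
                g.add_node(
                    name,
                    kind=EXTERNAL,
                    label=name,
                    description="",
                    go_terms=(),
                    pathways=(),
                    is_seed=False,
                    distance=0,
                )

    store_edges: dict[frozenset[str], EvidenceEdge] = {}
    for edge in graph.store.edges:
        store_edges.setdefault(frozenset((edge.a, edge.b)), edge)

    counter = 0
    for a, b, interaction in raw_edges:
        u, v = mapping[a], mapping[b]
        match = store_edges.get(frozenset((u, v)))
        if match is not None and match.edge_id not in [
            k for _, _, k in g.edges(keys=True)
        ]:
            g.add_edge(
                match.a, match.b, key=match.edge_id,
                rel_type=match.rel_type, src=match.a, dst=match.b,
                evidence=match.evidence, dashed=match.rel_type == CODING,
            )
        elif match is None:
            counter += 1
            key = f"imported:{counter:04d}"
            g.add_edge(
                u, v, key=key,
                rel_type=IMPORTED, src=u, dst=v,
                evidence=(), dashed=False,
            )
    return BuiltNetwork(graph=g, query=q, unresolved_tokens=report, conversion_stats=stats)
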