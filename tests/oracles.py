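"""Independent reference implementations used to cross-check the package.

Each oracle recomputes a quantity by a different route than the library:
expansion reachability by weighted Dijkstra over a re-parsed relation
table, equivalence classes by O(n^2) pairwise neighborhood comparison,
clustering by O(n^3) triangle enumeration, and path lengths by networkx's
weighted shortest paths on a collapsed graph.
"""

from __future__ import annotations

import csv
import itertools
from pathlib import Path

import networkx as nx

WEIGHT = {"coding": 0, "ppi": 1, "pdna": 1, "imported": 1}


def read_relation_rows(relations_tsv: Path) -> list[dict]:
    rows = []
    with open(relations_tsv, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                continue
            rows.append(dict(zip(header, row)))
    return rows


def row_passes(row: dict, sources: frozenset, methods: frozenset, rel_types: frozenset) -> bool:
    return (
        row["rel_type"] in rel_types
        and (not sources or row["source_db"] in sources)
        and (not methods or row["method"] in methods)
    )


def filtered_weighted_graph(
    relations_tsv: Path,
    all_nodes,
    sources: frozenset = frozenset(),
    methods: frozenset = frozenset(),
    rel_types: frozenset = frozenset({"coding", "ppi", "pdna"}),
) -> nx.Graph:
    """Simple weighted graph over filter-surviving rows (min weight wins)."""
    g = nx.Graph()
    g.add_nodes_from(all_nodes)
    for row in read_relation_rows(relations_tsv):
        if not row_passes(row, sources, methods, rel_types):
            continue
        a, b, w = row["a"], row["b"], WEIGHT[row["rel_type"]]
        if g.has_edge(a, b):
            g[a][b]["weight"] = min(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return g


def reachable_within(
    relations_tsv: Path, all_nodes, seeds, n: int, **filter_kw
) -> set[str]:
    """Node set within weighted distance n of the seed set (Dijkstra)."""
    g = filtered_weighted_graph(relations_tsv, all_nodes, **filter_kw)
    dist = nx.multi_source_dijkstra_path_length(g, set(seeds), weight="weight")
    return {node for node, d in dist.items() if d <= n}


def neighbor_set(relations_tsv: Path, node: str, **filter_kw) -> set[tuple[str, str]]:
    """(neighbor, rel_type) pairs incident to node, by raw row scan."""
    out = set()
    sources = filter_kw.get("sources", frozenset())
    methods = filter_kw.get("methods", frozenset())
    rel_types = filter_kw.get("rel_types", frozenset({"coding", "ppi", "pdna"}))
    for row in read_relation_rows(relations_tsv):
        if not row_passes(row, sources, methods, rel_types):
            continue
        if node == row["a"]:
            out.add((row["b"], row["rel_type"]))
        if node == row["b"]:
            out.add((row["a"], row["rel_type"]))
    return out


def pairwise_equivalence_classes(simple: nx.Graph) -> set[frozenset]:
    """Equivalence classes by O(n^2) comparison of open neighborhoods."""
    nodes = sorted(simple.nodes)
    nbr = {v: set(simple[v]) - {v} for v in nodes}
    assigned: dict[str, set[str]] = {}
    for u, v in itertools.combinations(nodes, 2):
        if nbr[u] == nbr[v]:
            group = assigned.get(u) or assigned.get(v) or {u}
            group.update((u, v))
            assigned[u] = assigned[v] = group
    return {frozenset(g) for g in assigned.values()}


def clustering_bruteforce(simple: nx.Graph) -> dict[str, float]:
    """Local clustering coefficients by explicit triangle enumeration."""
    out = {}
    for v in simple.nodes:
        nbrs = sorted(set(simple[v]) - {v})
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        t = sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if simple.has_edge(a, b) and a != b
        )
        out[v] = 2.0 * t / (k * (k - 1))
    return out


def weighted_path_lengths(net, selected) -> dict[tuple[str, str], float]:
    """Pairwise shortest lengths under the 0/1 convention, via networkx."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for _, _, d in net.graph.edges(data=True):
        u, v, w = d["src"], d["dst"], WEIGHT[d["rel_type"]]
        if g.has_edge(u, v):
            g[u][v]["weight"] = min(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    out = {}
    selected = sorted(set(selected))
    for i, src in enumerate(selected):
        lengths = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for dst in selected[i + 1:]:
            out[(src, dst)] = lengths.get(dst, float("inf"))
    return out
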