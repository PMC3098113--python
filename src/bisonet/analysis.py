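"""Client-side analyses of a built network.

* **Equivalent nodes** — structural equivalence classes: nodes whose open
  neighborhoods (self excluded) are identical.  Functionally related genes
  frequently land in one class, and grouping them simplifies dense views.
* **Shortest paths** — all pairs among a selected node subset, under the
  same 0/1 edge-length convention used during expansion (coding edges are
  free), with a deterministic lexicographically-smallest witness path.
* **Topology statistics** — degree, degree histogram, and the local
  clustering coefficient C(v) = 2 t(v) / (k(v) (k(v) - 1)) where t(v)
  counts triangles through v (defined as 0 for degree < 2).

All three operate on the network as displayed: parallel edges collapsed,
every relation type treated alike; self-loops are ignored for clustering
and counted once toward degree.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx

from .builder import BuildError, BuiltNetwork
from .datastore import CODING

__all__ = [
    "EquivalenceSet",
    "PathResult",
    "TopologyReport",
    "find_equivalent_sets",
    "shortest_paths",
    "network_statistics",
]


@dataclass(frozen=True)
class EquivalenceSet:
    members: tuple[str, ...]
    shared_neighborhood: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


class PathResult(NamedTuple):
    pair: tuple[str, str]
    length: float  # math.inf when unreachable
    path: tuple[str, ...] | None


@dataclass
class TopologyReport:
    degree: dict[str, int]
    degree_histogram: dict[int, int]
    clustering: dict[str, float]
    mean_clustering: float

    def to_tsv(self) -> str:
        lines = ["node\tdegree\tclustering"]
        for node in sorted(self.degree):
            lines.append(f"{node}\t{self.degree[node]}\t{self.clustering[node]:.6g}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
                "clustering": self.clustering,
                "mean_clustering": self.mean_clustering,
            },
            indent=2,
            sort_keys=True,
        )


def find_equivalent_sets(net: BuiltNetwork) -> list[EquivalenceSet]:
    """Partition nodes by identical open neighborhood; keep classes >= 2.

    The signature of a node is its neighbor set excluding itself, so a
    self-loop does not distinguish otherwise-equivalent nodes.  Isolated
    nodes share the empty neighborhood and group together.  Classes are
    returned largest first, ties broken by member order.
    """
    if net.n_nodes == 0:
        raise BuildError("network is empty")
    s = net.simple_graph()
    signatures: dict[frozenset[str], list[str]] = {}
    for node in s.nodes:
        sig = frozenset(s[node]) - {node}
        signatures.setdefault(sig, []).append(node)
    sets = [
        EquivalenceSet(members=tuple(sorted(members)), shared_neighborhood=tuple(sorted(sig)))
        for sig, members in signatures.items()
        if len(members) >= 2
    ]
    sets.sort(key=lambda e: (-e.size, e.members))
    return sets


def _edge_weight(net: BuiltNetwork, u: str, v: str) -> int:
    # minimum over parallel edges; coding relations are free, every other
    # relation (ppi, pdna, imported) costs one step
    return min(
        0 if attrs["rel_type"] == CODING else 1
        for attrs in net.graph[u][v].values()
    )


def _lexicographic_dijkstra(net: BuiltNetwork, source: str) -> dict[str, tuple[int, tuple[str, ...]]]:
    """Distances and lexicographically-smallest shortest paths from source.

    Priority queue entries are (distance, path); because every path from
    the source shares its first node and extension appends to the right,
    popping in (distance, path) order settles each node with its smallest
    witness among all shortest paths.
    """
    best: dict[str, tuple[int, tuple[str, ...]]] = {}
    heap: list[tuple[int, tuple[str, ...]]] = [(0, (source,))]
    while heap:
        d, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (d, path)
        for nbr in sorted(net.graph[node]):
            if nbr in best or nbr == node:
                continue
            heapq.heappush(heap, (d + _edge_weight(net, node, nbr), path + (nbr,)))
    return best


def shortest_paths(net: BuiltNetwork, selected: Iterable[str]) -> list[PathResult]:
    """Shortest path for every unordered pair of selected nodes.

    Lengths use the 0/1 convention (a gene reaches its own product at
    length 0).  Unreachable pairs get infinite length and no witness.
    """
    selected = sorted(set(selected))
    if len(selected) < 2:
        raise BuildError("shortest_paths requires at least two selected nodes")
    unknown = [s for s in selected if s not in net.graph]
    if unknown:
        raise BuildError(f"selected nodes not in network: {unknown}")

    results: list[PathResult] = []
    for i, src in enumerate(selected):
        reach = _lexicographic_dijkstra(net, src)
        for dst in selected[i + 1:]:
            if dst in reach:
                d, path = reach[dst]
                results.append(PathResult((src, dst), d, path))
            else:
                results.append(PathResult((src, dst), math.inf, None))
    return results


def network_statistics(net: BuiltNetwork) -> TopologyReport:
    """Degree and clustering over the collapsed simple graph.

    Degree counts distinct neighbors, a self-loop contributing one.
    Clustering is the standard local coefficient computed on the loopless
    simple graph; the mean averages over all nodes, counting degree-<2
    nodes as zero.
    """
    s = net.simple_graph()
    degree = {node: len(s[node]) for node in s.nodes}
    histogram: dict[int, int] = {}
    for k in degree.values():
        histogram[k] = histogram.get(k, 0) + 1

    loopless = net.simple_graph(drop_loops=True)
    clustering = {n: float(c) for n, c in nx.clustering(loopless).items()}
    n = loopless.number_of_nodes()
    mean = sum(clustering.values()) / n if n else 0.0
    return TopologyReport(
        degree=degree,
        degree_histogram=histogram,
        clustering=clustering,
        mean_clustering=mean,
    )
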