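"""Network serialization and standard-format export.

The exchange format is a versioned XML document (optionally gzipped)
carrying everything a client needs to redisplay and re-analyze a network:
per-node annotation (kind, label, description, GO terms, pathways, seed
flag, distance from the seed set) and per-edge provenance (relation type,
stored direction, and each evidence item's source database, experimental
method and PubMed references).  Serialization is deterministic — the same
network always yields the same bytes — and ``parse_network`` is its exact
inverse.

For downstream visualization the network also exports to SIF (node labels
and interaction types, one edge per line) and GraphML (all node and edge
attributes flattened to strings), both directly loadable by Cytoscape.
Coding relations keep their dashed-arrow render hint as an edge attribute.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import networkx as nx
from lxml import etree

from .builder import BuildError, BuiltNetwork, IMPORTED, NetworkQuery
from .datastore import CODING, Evidence, PDNA, PPI
from .supergraph import EdgeFilter

__all__ = [
    "SCHEMA_VERSION",
    "FormatError",
    "serialize_network",
    "parse_network",
    "export",
]

SCHEMA_VERSION = "1.0"
_KNOWN_REL_TYPES = (CODING, PPI, PDNA, IMPORTED)


class FormatError(ValueError):
    """Raised for malformed or incompatible serialized networks."""


def _join(values) -> str:
    return "|".join(str(v) for v in values)


def serialize_network(net: BuiltNetwork, compress: bool = False) -> bytes:
    """Serialize a network to XML bytes, gzipped when ``compress``.

    Output is byte-identical across calls for the same network: nodes and
    edges are emitted in sorted order and the gzip header carries no
    timestamp.
    """
    root = etree.Element("network", schema_version=SCHEMA_VERSION)
    if net.query is not None:
        q = net.query
        etree.SubElement(
            root,
            "query",
            organism=str(q.organism),
            identify_kinds=_join(sorted(q.identify_kinds)),
            sources=_join(sorted(q.filter.sources)),
            methods=_join(sorted(q.filter.methods)),
            rel_types=_join(sorted(q.filter.rel_types)),
            distance=str(q.distance),
            output_mode=q.output_mode,
        )
    if net.conversion_stats is not None:
        etree.SubElement(
            root, "conversion_stats",
            **{k: str(v) for k, v in sorted(net.conversion_stats.items())},
        )

    nodes_el = etree.SubElement(root, "nodes")
    for node in sorted(net.graph.nodes):
        d = net.graph.nodes[node]
        el = etree.SubElement(
            nodes_el,
            "node",
            id=node,
            kind=d["kind"],
            label=d["label"],
            seed="true" if d["is_seed"] else "false",
            distance=str(d["distance"]),
        )
        etree.SubElement(el, "description").text = d["description"] or None
        etree.SubElement(el, "go").text = _join(d["go_terms"]) or None
        etree.SubElement(el, "pathways").text = _join(d["pathways"]) or None

    edges_el = etree.SubElement(root, "edges")
    edge_items = sorted(
        ((k, d) for _, _, k, d in net.graph.edges(keys=True, data=True)),
        key=lambda item: item[0],
    )
    for key, d in edge_items:
        el = etree.SubElement(
            edges_el,
            "edge",
            id=key,
            rel_type=d["rel_type"],
            src=d["src"],
            dst=d["dst"],
            dashed="true" if d["dashed"] else "false",
        )
        for ev in d["evidence"]:
            etree.SubElement(
                el, "evidence",
                source_db=ev.source_db,
                method=ev.method,
                pubmed=_join(ev.pubmed_ids),
            )

    unresolved_el = etree.SubElement(root, "unresolved")
    for token, status in sorted(net.unresolved_tokens):
        etree.SubElement(unresolved_el, "token", value=token, status=status)

    payload = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if compress:
        payload = gzip.compress(payload, mtime=0)
    return payload


def parse_network(doc: bytes) -> BuiltNetwork:
    """Inverse of :func:`serialize_network` (gzip detected automatically)."""
    if doc[:2] == b"\x1f\x8b":
        try:
            doc = gzip.decompress(doc)
        except (OSError, EOFError):
            raise FormatError("corrupt payload: gzip stream is damaged or truncated") from None
    try:
        root = etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from None
    if root.tag != "network":
        raise FormatError(f"unexpected root element {root.tag!r}")
    version = root.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})")

    query = None
    q_el = root.find("query")
    if q_el is not None:
        def split(attr: str) -> frozenset[str]:
            raw = q_el.get(attr, "")
            return frozenset(v for v in raw.split("|") if v)

        query = NetworkQuery(
            organism=int(q_el.get("organism")),
            identify_kinds=split("identify_kinds"),
            filter=EdgeFilter(
                sources=split("sources"),
                methods=split("methods"),
                rel_types=split("rel_types"),
            ),
            distance=int(q_el.get("distance")),
            output_mode=q_el.get("output_mode"),
        )

    stats = None
    stats_el = root.find("conversion_stats")
    if stats_el is not None:
        stats = {k: int(v) for k, v in stats_el.attrib.items()}

    g = nx.MultiGraph()
    for el in root.iterfind("nodes/node"):
        def text(tag: str) -> str:
            child = el.find(tag)
            return child.text or "" if child is not None else ""

        def tup(tag: str) -> tuple[str, ...]:
            raw = text(tag)
            return tuple(v for v in raw.split("|") if v) if raw else ()

        g.add_node(
            el.get("id"),
            kind=el.get("kind"),
            label=el.get("label"),
            description=text("description"),
            go_terms=tup("go"),
            pathways=tup("pathways"),
            is_seed=el.get("seed") == "true",
            distance=int(el.get("distance")),
        )

    for el in root.iterfind("edges/edge"):
        rel = el.get("rel_type")
        if rel not in _KNOWN_REL_TYPES:
            raise FormatError(f"unknown rel_type {rel!r} in edge {el.get('id')!r}")
        src, dst = el.get("src"), el.get("dst")
        for endpoint in (src, dst):
            if endpoint not in g:
                raise FormatError(f"edge {el.get('id')!r} references unknown node {endpoint!r}")
        evidence = tuple(
            Evidence(
                source_db=ev.get("source_db"),
                method=ev.get("method", ""),
                pubmed_ids=tuple(int(p) for p in ev.get("pubmed", "").split("|") if p),
            )
            for ev in el.iterfind("evidence")
        )
        g.add_edge(
            src, dst, key=el.get("id"),
            rel_type=rel, src=src, dst=dst,
            evidence=evidence, dashed=el.get("dashed") == "true",
        )

    unresolved = [
        (el.get("value"), el.get("status")) for el in root.iterfind("unresolved/token")
    ]
    return BuiltNetwork(graph=g, query=query, unresolved_tokens=unresolved, conversion_stats=stats)


# ---------------------------------------------------------------------------
# standard-format export


def _sif_names(net: BuiltNetwork) -> dict[str, str]:
    """Map node ids to display labels, disambiguating collisions."""
    by_label: dict[str, list[str]] = {}
    for node, d in net.graph.nodes(data=True):
        by_label.setdefault(d["label"], []).append(node)
    names = {}
    for label, nodes in by_label.items():
        if len(nodes) == 1:
            names[nodes[0]] = label
        else:
            warnings.warn(
                f"label {label!r} shared by {len(nodes)} nodes; suffixing internal ids",
                stacklevel=3,
            )
            for node in nodes:
                names[node] = f"{label}#{node}"
    return names


def export(net: BuiltNetwork, path: str | Path, format: str) -> Path:
    """Write the network as ``sif`` or ``graphml`` and return the path."""
    path = Path(path)
    if format == "sif":
        names = _sif_names(net)
        lines = []
        connected = set()
        for u, v, d in net.graph.edges(data=True):
            lines.append(f"{names[d['src']]}\t{d['rel_type']}\t{names[d['dst']]}")
            connected.update((u, v))
        for node in net.graph.nodes:
            if node not in connected:
                lines.append(names[node])
        path.write_text("\n".join(sorted(lines)) + "\n", encoding="utf-8")
    elif format == "graphml":
        flat = nx.MultiGraph()
        for node, d in net.graph.nodes(data=True):
            flat.add_node(
                node,
                kind=d["kind"],
                label=d["label"],
                description=d["description"],
                go_terms=_join(d["go_terms"]),
                pathways=_join(d["pathways"]),
                is_seed=d["is_seed"],
                distance=d["distance"],
            )
        for u, v, k, d in net.graph.edges(keys=True, data=True):
            flat.add_edge(
                u, v, key=k,
                rel_type=d["rel_type"],
                src=d["src"],
                dst=d["dst"],
                dashed=d["dashed"],
                sources=_join(sorted({ev.source_db for ev in d["evidence"]})),
                methods=_join(sorted({ev.method for ev in d["evidence"] if ev.method})),
                pubmed=_join(sorted({p for ev in d["evidence"] for p in ev.pubmed_ids})),
            )
        nx.write_graphml(flat, path)
    else:
        raise BuildError(f"unknown export format {format!r}")
    return path
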