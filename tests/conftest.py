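from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pytest

from bisonet import (
    BuiltNetwork,
    DataStore,
    SuperGraph,
    TranslationTable,
    assemble_supergraph,
    build_translation_table,
    load_datastore,
    make_random_store,
    make_worked_examples,
)


@dataclass
class StoreBundle:
    directory: Path
    manifest: dict
    store: DataStore
    graph: SuperGraph
    table: TranslationTable


def _bundle(directory: Path, manifest: dict) -> StoreBundle:
    store = load_datastore(directory)
    return StoreBundle(
        directory=directory,
        manifest=manifest,
        store=store,
        graph=assemble_supergraph(store),
        table=build_translation_table(store.identifiers, store.entities),
    )


@pytest.fixture(scope="session")
def worked(tmp_path_factory) -> StoreBundle:
    """The hand-specified demonstration store (CPM / HBA / HLA-A neighborhoods)."""
    directory = tmp_path_factory.mktemp("worked")
    manifest = make_worked_examples(directory)
    return _bundle(directory, manifest)


@pytest.fixture(scope="session")
def random_bundle(tmp_path_factory) -> StoreBundle:
    """A mid-size seeded random store for property tests."""
    directory = tmp_path_factory.mktemp("random")
    manifest = make_random_store(
        directory,
        seed=7,
        n_genes=40,
        ppi_density=0.05,
        pdna_density=0.01,
        alias_ambiguity_rate=0.1,
    )
    return _bundle(directory, manifest)


def make_network(
    edges: list[tuple[str, str]],
    nodes: list[str] | None = None,
    rel_type: str = "ppi",
) -> BuiltNetwork:
    """Build a bare network for analysis tests (generic attributes)."""
    g = nx.MultiGraph()
    for node in nodes or []:
        _add_node(g, node)
    for i, (u, v) in enumerate(edges):
        _add_node(g, u)
        _add_node(g, v)
        g.add_edge(u, v, key=f"E{i:03d}", rel_type=rel_type, src=u, dst=v,
                   evidence=(), dashed=rel_type == "coding")
    return BuiltNetwork(graph=g)


def _add_node(g: nx.MultiGraph, node: str) -> None:
    if node not in g:
        g.add_node(node, kind="protein", label=node, description="",
                   go_terms=(), pathways=(), is_seed=False, distance=0)
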