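"""Network construction: identify, expand, project, expand-again, convert."""

from __future__ import annotations

import random

import pytest

import oracles
from bisonet import (
    BuildError,
    EdgeFilter,
    NetworkQuery,
    build_network,
    convert_network,
    expand,
    expand_network,
    identify_seeds,
    project,
)
from bisonet.builder import GENES_AND_PROTEINS, GENES_ONLY, PROTEINS_ONLY
from bisonet.datastore import (
    BioEntity,
    DataStore,
    Evidence,
    EvidenceEdge,
)
from bisonet.interop import export
from bisonet.supergraph import assemble_supergraph

HUMAN = 9606


def q(**kw) -> NetworkQuery:
    kw.setdefault("organism", HUMAN)
    return NetworkQuery(**kw)


class TestIdentifySeeds:
    def test_single_gene_token(self, worked):
        seeds, report = identify_seeds(["CPM"], q(identify_kinds={"gene"}),
                                       worked.table, worked.graph)
        assert seeds == {"G_CPM"} and report == []

    def test_mixed_kind_tokens(self, worked):
        seeds, _ = identify_seeds(["P01133", "EGF"], q(), worked.table, worked.graph)
        assert seeds == {"G_EGF", "P_EGF"}

    def test_unresolvable_tokens_are_reported_not_fatal(self, worked):
        seeds, report = identify_seeds(["garbage1", "garbage2", "CPM"], q(),
                                       worked.table, worked.graph)
        assert seeds == {"G_CPM"}
        assert sorted(report) == [("garbage1", "unresolved"), ("garbage2", "unresolved")]

    def test_empty_token_list_is_an_error(self, worked):
        with pytest.raises(BuildError, match="no input identifiers"):
            identify_seeds([], q(), worked.table, worked.graph)

    def test_all_unresolvable_fails_downstream(self, worked):
        with pytest.raises(BuildError, match="no seeds identified"):
            build_network(["garbage1", "garbage2"], q(), worked.store,
                          graph=worked.graph, table=worked.table)


class TestExpand:
    def test_cpm_distance1_reaches_figure_neighborhood(self, worked):
        sub = expand(worked.graph, {"G_CPM"}, EdgeFilter(), 1)
        genes = {n for n in sub.distances if worked.graph.entity(n).kind == "gene"}
        assert genes == {"G_CPM", "G_HBA1", "G_HBA2", "G_EGF"}

    def test_distance0_includes_products_via_coding(self, worked):
        sub = expand(worked.graph, {"G_HLA_A"}, EdgeFilter(), 0)
        assert set(sub.distances) == {"G_HLA_A", "P_1A01", "P_1A02", "P_1A03"}
        assert all(d == 0 for d in sub.distances.values())

    def test_seeds_always_present_at_distance_zero(self, worked):
        sub = expand(worked.graph, {"P_UBIQ", "G_CPM"}, EdgeFilter(), 2)
        assert sub.distances["P_UBIQ"] == 0 and sub.distances["G_CPM"] == 0

    def test_empty_seed_set_is_an_error(self, worked):
        with pytest.raises(BuildError):
            expand(worked.graph, set(), EdgeFilter(), 1)

    def test_monotone_in_distance(self, random_bundle):
        seeds = {sorted(random_bundle.store.entities)[0]}
        previous: set = set()
        for n in range(4):
            nodes = set(expand(random_bundle.graph, seeds, EdgeFilter(), n).distances)
            assert previous <= nodes
            previous = nodes

    def test_node_set_matches_dijkstra_oracle(self, random_bundle):
        rng = random.Random(23)
        nodes = sorted(random_bundle.store.entities)
        relations = random_bundle.directory / "relations.tsv"
        for _ in range(15):
            seeds = set(rng.sample(nodes, rng.randint(1, 3)))
            n = rng.randint(0, 3)
            rel_types = frozenset(rng.sample(["coding", "ppi", "pdna"], rng.randint(1, 3)))
            f = EdgeFilter(rel_types=rel_types)
            got = set(expand(random_bundle.graph, seeds, f, n).distances)
            expected = oracles.reachable_within(
                relations, nodes, seeds, n, rel_types=rel_types)
            assert got == expected

    def test_coding_zero_property(self, random_bundle):
        """Products of any included gene sit at the gene's own distance."""
        nodes = sorted(random_bundle.store.entities)
        sub = expand(random_bundle.graph, {nodes[0], nodes[5]}, EdgeFilter(), 2)
        for edge in sub.edges:
            if edge.rel_type != "coding":
                continue
            assert sub.distances[edge.a] == sub.distances[edge.b]

    def test_induced_edges_interconnect_seeds(self, worked):
        # HBA1 and HBA2 products interact; expanding from both seeds at N=0
        # must include that edge even though no traversal crosses it
        sub = expand(worked.graph, {"G_HBA1", "G_HBA2"}, EdgeFilter(), 0)
        ppi = [e for e in sub.edges if e.rel_type == "ppi"]
        assert any({e.a, e.b} == {"P_HBA1", "P_HBA2"} for e in ppi)


def _toy_isoform_store() -> DataStore:
    ev = (Evidence(source_db="DIP", method="two hybrid", pubmed_ids=(1,)),)
    entities = {
        "G1": BioEntity("G1", "gene", HUMAN, "TOY1"),
        "P1": BioEntity("P1", "protein", HUMAN, "TOY1A_HUMAN"),
        "P2": BioEntity("P2", "protein", HUMAN, "TOY1B_HUMAN"),
    }
    edges = [
        EvidenceEdge("C1", "coding", "G1", "P1", ev),
        EvidenceEdge("C2", "coding", "G1", "P2", ev),
        EvidenceEdge("I1", "ppi", "P1", "P2", ev),
    ]
    return DataStore(entities=entities, identifiers=[], edges=edges)


class TestProject:
    def test_passthrough_keeps_everything_and_flags_coding_dashed(self, worked):
        sub = expand(worked.graph, {"G_CPM"}, EdgeFilter(), 1)
        net = project(sub, GENES_AND_PROTEINS)
        assert set(net.graph.nodes) == set(sub.distances)
        dashed = {k for _, _, k, d in net.graph.edges(keys=True, data=True) if d["dashed"]}
        coding = {e.edge_id for e in sub.edges if e.rel_type == "coding"}
        assert dashed == coding

    def test_genes_only_gives_four_figure_nodes(self, worked):
        sub = expand(worked.graph, {"G_CPM"}, EdgeFilter(), 1)
        net = project(sub, GENES_ONLY)
        assert sorted(net.labels().values()) == ["CPM", "EGF", "HBA1", "HBA2"]

    def test_within_gene_contraction_drops_self_edge(self):
        store = _toy_isoform_store()
        g = assemble_supergraph(store)
        sub = expand(g, {"G1"}, EdgeFilter(), 1)
        net = project(sub, GENES_ONLY)
        assert set(net.graph.nodes) == {"G1"}
        assert net.n_edges == 0

    def test_proteins_only_counts_match_kind_filter(self, random_bundle):
        nodes = sorted(random_bundle.store.entities)
        sub = expand(random_bundle.graph, {nodes[0], nodes[7]}, EdgeFilter(), 2)
        net = project(sub, PROTEINS_ONLY)
        expected = {
            n for n in sub.distances
            if random_bundle.store.entities[n].kind == "protein"
        }
        assert set(net.graph.nodes) == expected

    def test_proteins_only_reattaches_pdna_to_products(self, worked):
        sub = expand(worked.graph, {"G_GATA1", "G_HBA1"}, EdgeFilter(), 1)
        net = project(sub, PROTEINS_ONLY)
        pdna = [d for _, _, d in net.graph.edges(data=True) if d["rel_type"] == "pdna"]
        assert any(d["src"] == "P_GATA1" and d["dst"] == "P_HBA1" for d in pdna)

    def test_projection_conservation(self, random_bundle):
        """Mixed node count = gene-level + protein-level counts when every
        protein has a coding gene (guaranteed by the generator)."""
        nodes = sorted(random_bundle.store.entities)
        sub = expand(random_bundle.graph, {nodes[3]}, EdgeFilter(), 2)
        both = project(sub, GENES_AND_PROTEINS)
        genes = project(sub, GENES_ONLY)
        prots = project(sub, PROTEINS_ONLY)
        # gene-level projection may pull in coding genes that were not in the
        # mixed view; restrict the comparison to the subgraph's own nodes
        gene_nodes_in_sub = set(genes.graph.nodes) & set(sub.distances)
        assert both.n_nodes == len(gene_nodes_in_sub) + prots.n_nodes

    def test_unknown_mode_is_an_error(self, worked):
        sub = expand(worked.graph, {"G_CPM"}, EdgeFilter(), 1)
        with pytest.raises(BuildError, match="unknown output mode"):
            project(sub, "nonsense")


class TestBuildNetwork:
    def test_figure_network_from_cpm(self, worked):
        net = build_network(["CPM"], q(identify_kinds={"gene"}, distance=1,
                                       output_mode=GENES_ONLY),
                            worked.store, graph=worked.graph, table=worked.table)
        assert net.n_nodes == 4
        assert net.seeds() == {"G_CPM"}
        assert net.node_attrs("G_CPM")["distance"] == 0

    def test_multi_isoform_and_multi_gene_protein_network(self, worked):
        net = build_network(["HLA-A"], q(identify_kinds={"gene"}, distance=1),
                            worked.store, graph=worked.graph, table=worked.table)
        labels = set(net.labels().values())
        assert {"HLA-A", "1A01_HUMAN", "1A02_HUMAN", "1A03_HUMAN", "UBIQ_HUMAN"} <= labels
        coding_into_ubiq = [
            d for _, _, d in net.graph.edges(data=True)
            if d["rel_type"] == "coding" and d["dst"] == "P_UBIQ"
        ]
        assert len(coding_into_ubiq) == 2

    def test_annotation_carried_onto_nodes(self, worked):
        net = build_network(["EGF"], q(identify_kinds={"gene"}, distance=0),
                            worked.store, graph=worked.graph, table=worked.table)
        attrs = net.node_attrs("G_EGF")
        assert attrs["go_terms"] and attrs["pathways"] and attrs["description"]


class TestExpandNetwork:
    def _cpm_net(self, worked):
        return build_network(["CPM"], q(identify_kinds={"gene"}, distance=1,
                                        output_mode=GENES_ONLY),
                             worked.store, graph=worked.graph, table=worked.table)

    def test_expanding_added_nodes_grows_strict_superset(self, worked):
        net = self._cpm_net(worked)
        grown = expand_network(net, ["G_HBA1", "G_HBA2", "G_EGF"],
                               q(distance=1, output_mode=GENES_ONLY), worked.graph)
        assert net.nodes < grown.nodes
        assert net.node_attrs("G_CPM")["is_seed"]

    def test_expand_all_at_distance_zero_is_idempotent(self, worked):
        net = self._cpm_net(worked)
        same = expand_network(net, sorted(net.nodes),
                              q(distance=0, output_mode=GENES_ONLY), worked.graph)
        assert same.nodes == net.nodes
        assert same.n_edges == net.n_edges

    def test_union_equivalence_with_two_step_build(self, worked):
        """Expanding every node of an N=1 network by one more step reaches
        exactly the N=2 network of the same seed (mixed representation)."""
        one = build_network(["CPM"], q(distance=1), worked.store,
                            graph=worked.graph, table=worked.table)
        grown = expand_network(one, sorted(one.nodes), q(distance=1), worked.graph)
        two = build_network(["CPM"], q(distance=2), worked.store,
                            graph=worked.graph, table=worked.table)
        assert grown.nodes == two.nodes

    def test_distances_are_minimized_on_union(self, worked):
        net = self._cpm_net(worked)
        grown = expand_network(net, ["G_EGF"], q(distance=1, output_mode=GENES_ONLY),
                               worked.graph)
        # EGF is selected, so it becomes a distance-0 origin in the update
        assert grown.node_attrs("G_EGF")["distance"] == 0
        assert grown.node_attrs("G_CPM")["distance"] == 0  # preserved minimum

    def test_empty_selection_is_an_error(self, worked):
        with pytest.raises(BuildError, match="no nodes selected"):
            expand_network(self._cpm_net(worked), [], q(), worked.graph)


class TestConvertNetwork:
    def test_two_column_edge_list(self, worked):
        net = convert_network(["EGF\tCPM"], q(identify_kinds={"gene"}),
                              worked.store, graph=worked.graph, table=worked.table)
        assert set(net.graph.nodes) == {"G_EGF", "G_CPM"}
        assert net.node_attrs("G_EGF")["description"]
        rels = [d["rel_type"] for _, _, d in net.graph.edges(data=True)]
        assert rels == ["imported"]
        assert net.conversion_stats["resolved"] == 2

    def test_store_backed_edges_inherit_evidence(self, worked):
        net = convert_network(["EGF_HUMAN\tEGFR_HUMAN"], q(identify_kinds={"protein"}),
                              worked.store, graph=worked.graph, table=worked.table)
        (_, _, d), = net.graph.edges(data=True)
        assert d["rel_type"] == "ppi" and len(d["evidence"]) == 2

    def test_empty_input_gives_empty_network(self, worked):
        net = convert_network([], q(), worked.store,
                              graph=worked.graph, table=worked.table)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_unresolved_names_kept_and_flagged(self, worked):
        net = convert_network(["EGF\tNOT_A_GENE"], q(identify_kinds={"gene"}),
                              worked.store, graph=worked.graph, table=worked.table)
        assert net.node_attrs("NOT_A_GENE")["kind"] == "external"
        assert ("NOT_A_GENE", "unresolved") in net.unresolved_tokens

    def test_sif_export_round_trip_preserves_node_set(self, worked, tmp_path):
        net = build_network(["CPM"], q(identify_kinds={"gene"}, distance=1,
                                       output_mode=GENES_ONLY),
                            worked.store, graph=worked.graph, table=worked.table)
        sif = export(net, tmp_path / "net.sif", "sif")
        back = convert_network(sif, q(identify_kinds={"gene"}),
                               worked.store, graph=worked.graph, table=worked.table)
        assert back.nodes == net.nodes
        assert back.unresolved_tokens == []

    def test_unparseable_line_is_fatal_with_line_number(self, worked, tmp_path):
        bad = tmp_path / "bad.sif"
        bad.write_text("EGF\t\tCPM\n")
        with pytest.raises(BuildError, match="bad.sif:1"):
            convert_network(bad, q(), worked.store,
                            graph=worked.graph, table=worked.table)
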