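"""Datastore loading, validation and identifier disambiguation."""

from __future__ import annotations

import pytest

from bisonet import (
    BioEntity,
    DataStoreError,
    IdentifierRecord,
    build_translation_table,
    load_datastore,
    resolve,
)
from bisonet.datastore import (
    ENTITY_COLUMNS,
    IDENTIFIER_COLUMNS,
    RELATION_COLUMNS,
)

HUMAN, MOUSE = 9606, 10090


def _write(path, columns, rows):
    lines = ["\t".join(columns)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def _store_files(tmp_path, entities=(), identifiers=(), relations=()):
    _write(tmp_path / "entities.tsv", ENTITY_COLUMNS, entities)
    _write(tmp_path / "identifiers.tsv", IDENTIFIER_COLUMNS, identifiers)
    _write(tmp_path / "relations.tsv", RELATION_COLUMNS, relations)
    return tmp_path


class TestLoading:
    def test_worked_store_contains_figure_genes(self, worked):
        labels = {e.primary_label for e in worked.store.entities.values() if e.kind == "gene"}
        assert {"CPM", "HBA1", "HBA2", "EGF"} <= labels
        assert len(labels) >= 4

    def test_empty_store_loads_without_error(self, tmp_path):
        store = load_datastore(_store_files(tmp_path))
        assert store.entities == {} and store.edges == [] and store.identifiers == []

    def test_dangling_edge_endpoint_is_fatal_and_named(self, tmp_path):
        _store_files(
            tmp_path,
            entities=[("G1", "gene", HUMAN, "A", "", "", "", ""),
                      ("P1", "protein", HUMAN, "A_P", "", "", "", "")],
            relations=[("E1", "coding", "G1", "G999", "DB", "m", "1")],
        )
        with pytest.raises(DataStoreError, match="G999"):
            load_datastore(tmp_path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        _store_files(tmp_path)
        (tmp_path / "entities.tsv").write_text(
            "\t".join(ENTITY_COLUMNS) + "\nG1\tgene\t9606\n"
        )
        with pytest.raises(DataStoreError, match=r"entities\.tsv:2"):
            load_datastore(tmp_path)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(DataStoreError, match="not found"):
            load_datastore(tmp_path)

    def test_wrong_endpoint_kinds_rejected(self, tmp_path):
        _store_files(
            tmp_path,
            entities=[("G1", "gene", HUMAN, "A", "", "", "", ""),
                      ("G2", "gene", HUMAN, "B", "", "", "", "")],
            relations=[("E1", "ppi", "G1", "G2", "DB", "m", "")],
        )
        with pytest.raises(DataStoreError, match="endpoint kinds"):
            load_datastore(tmp_path)

    def test_loading_is_deterministic(self, worked):
        again = load_datastore(worked.directory)
        assert [e.edge_id for e in again.edges] == [e.edge_id for e in worked.store.edges]
        assert again.entities == worked.store.entities
        assert again.edges == worked.store.edges

    def test_duplicate_ppi_reports_merge_into_one_edge(self, worked):
        # the same CPM interaction is present under two edge ids and three
        # evidence rows; the loader must collapse them
        edges = [
            e for e in worked.store.edges
            if e.rel_type == "ppi" and {e.a, e.b} == {"P_CPM", "P_HBA1"}
        ]
        assert len(edges) == 1
        assert len(edges[0].evidence) == 3
        assert {ev.source_db for ev in edges[0].evidence} == {"HPRD", "BioGRID", "MINT"}


class TestTranslationTable:
    def test_multi_gene_alias_is_discarded(self, worked):
        assert worked.table.discarded.get("vh") == "multi-gene alias"

    def test_alias_colliding_with_other_symbol_is_discarded(self, worked):
        assert worked.table.discarded.get("ambx") == "alias-collides-with-symbol"
        assert resolve("AMBX", HUMAN, {"gene"}, worked.table).status == "discarded"

    def test_unambiguous_alias_resolves(self, worked):
        res = resolve("URG", HUMAN, {"gene"}, worked.table)
        assert res.ids == {"G_EGF"} and res.status == "resolved"

    def test_alias_equal_to_own_symbol_is_kept(self, worked):
        # same-gene alias/symbol coincidence carries no ambiguity
        res = resolve("HP", HUMAN, {"gene"}, worked.table)
        assert res.ids == {"G_HP"}

    def test_no_token_in_both_resolved_and_discarded(self, worked):
        assert not set(worked.table.resolved) & set(worked.table.discarded)

    def test_record_conservation(self, worked):
        table = worked.table
        kept = sum(len(v) for v in table.resolved_exact.values())
        kept += sum(len(v) for v in table.resolved_folded.values())
        assert kept + table.n_discarded_records == table.n_records

    def test_corrupt_duplicate_non_alias_token_is_fatal(self):
        entities = {
            "G1": BioEntity("G1", "gene", HUMAN, "A"),
            "G2": BioEntity("G2", "gene", HUMAN, "B"),
        }
        records = [
            IdentifierRecord("NM_1", "refseq_accession", "gene", "G1"),
            IdentifierRecord("NM_1", "refseq_accession", "gene", "G2"),
        ]
        with pytest.raises(DataStoreError, match="corrupt store"):
            build_translation_table(records, entities)

    def test_discard_soundness_on_random_store(self, random_bundle):
        """Every resolved token names at most one entity per kind (brute scan)."""
        table = random_bundle.table
        entities = random_bundle.store.entities
        for token, pairs in table.resolved.items():
            per_kind: dict[str, set[str]] = {}
            for target, _ in pairs:
                per_kind.setdefault(entities[target].kind, set()).add(target)
            for kind, targets in per_kind.items():
                assert len(targets) == 1, (token, kind, targets)

    def test_manifest_ambiguous_aliases_all_discarded(self, random_bundle):
        ambiguous = random_bundle.manifest["ambiguous_aliases"]
        assert ambiguous, "random store should contain deliberately ambiguous aliases"
        for token in ambiguous:
            assert random_bundle.table.discarded.get(token) == "multi-gene alias"


class TestResolve:
    def test_symbol_resolves_to_gene(self, worked):
        assert resolve("EGF", HUMAN, {"gene"}, worked.table).ids == {"G_EGF"}

    def test_uniprot_accession_resolves_to_protein(self, worked):
        assert resolve("P01133", HUMAN, {"protein"}, worked.table).ids == {"P_EGF"}

    def test_unknown_token_is_unresolved(self, worked):
        res = resolve("NO_SUCH_ID_XYZ", HUMAN, {"gene", "protein"}, worked.table)
        assert res.ids == frozenset() and res.status == "unresolved"

    @pytest.mark.parametrize(
        "kinds,expected",
        [({"gene"}, {"G_EGF"}), ({"protein"}, {"P_EGF"}), ({"gene", "protein"}, {"G_EGF", "P_EGF"})],
    )
    def test_refseq_protein_id_is_kind_dependent(self, worked, kinds, expected):
        assert resolve("NP_001954", HUMAN, kinds, worked.table).ids == expected

    def test_genbank_protein_accession_resolves_to_gene(self, worked):
        # the identifier catalogue types GenBank protein accessions as gene ids
        assert resolve("CAA28240", HUMAN, {"gene", "protein"}, worked.table).ids == {"G_EGF"}

    def test_symbols_match_case_insensitively(self, worked):
        assert resolve("cpm", HUMAN, {"gene"}, worked.table).ids == {"G_CPM"}
        assert resolve("hla-a", HUMAN, {"gene"}, worked.table).ids == {"G_HLA_A"}

    def test_accessions_match_case_sensitively(self, worked):
        assert resolve("p01133", HUMAN, {"protein"}, worked.table).status == "unresolved"

    def test_resolution_is_organism_scoped(self, worked):
        assert resolve("Trp53", MOUSE, {"gene"}, worked.table).ids == {"G_TRP53M"}
        assert resolve("Trp53", HUMAN, {"gene"}, worked.table).status == "unresolved"
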