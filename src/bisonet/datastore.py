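"""Integrated gene/protein repository backed by plain TSV files.

The store holds three kinds of content:

* **bioentities** — gene and protein records, each with an opaque internal
  id, an NCBI taxon, a display label and functional annotation (GO terms,
  pathway ids, cross-references);
* **identifier records** — public tokens (gene symbols, Entrez GeneIDs,
  RefSeq/GenBank/UniGene/Uniprot accessions, gene aliases) mapped onto
  internal ids;
* **typed relations** — coding (gene → protein product), protein–protein
  interaction (undirected) and protein–DNA (protein → regulated gene)
  edges, each carrying per-source evidence (source database, experimental
  method label, PubMed references).

Identifier resolution goes through a *translation table* built from the
identifier records.  Gene aliases are the one identifier class where the
public namespaces collide: an alias naming more than one gene, or an alias
equal to the official symbol of a *different* gene, is ambiguous and the
token is discarded outright — it can no longer be used for identification,
and the affected genes stay reachable through their other identifiers.

File formats are documented in the module-level ``*_COLUMNS`` constants;
all files are UTF-8, tab-delimited, with a header row, and lines starting
with ``#`` are ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

__all__ = [
    "GENE",
    "PROTEIN",
    "CODING",
    "PPI",
    "PDNA",
    "REL_TYPES",
    "ID_TYPE_KIND",
    "CASE_INSENSITIVE_ID_TYPES",
    "BioEntity",
    "IdentifierRecord",
    "Evidence",
    "EvidenceEdge",
    "DataStore",
    "DataStoreError",
    "TranslationTable",
    "Resolution",
    "load_datastore",
    "build_translation_table",
    "resolve",
]

GENE = "gene"
PROTEIN = "protein"
ENTITY_KINDS = (GENE, PROTEIN)

CODING = "coding"  # gene -> protein it codes for; distance 0
PPI = "ppi"        # protein -- protein, undirected; distance 1
PDNA = "pdna"      # protein -> gene whose promoter it binds; distance 1
REL_TYPES = (CODING, PPI, PDNA)

#: identifier type -> entity kind it names.  ``gene_or_protein`` types may
#: have one record targeting the gene and one targeting the protein.
#: GenBank protein accessions resolve to the *gene* record: that is how the
#: public identifier catalogue types them, odd as it reads.
ID_TYPE_KIND: Mapping[str, str] = {
    "entrez_symbol": GENE,
    "entrez_geneid": GENE,
    "refseq_accession": GENE,
    "refseq_protein_id": "gene_or_protein",
    "gene_alias": GENE,
    "unigene_cluster": GENE,
    "genbank_accession": GENE,
    "genbank_protein_accession": GENE,
    "uniprot_id": PROTEIN,
    "uniprot_accession": PROTEIN,
    "uniprot_secondary_accession": PROTEIN,
}

#: Symbol and alias case varies across sources ("HLA-A" vs "hla-a"); these
#: types match case-insensitively.  Accession-style tokens are exact-match.
CASE_INSENSITIVE_ID_TYPES = frozenset({"entrez_symbol", "gene_alias"})

ENTITY_COLUMNS = (
    "internal_id", "kind", "taxon", "primary_label",
    "description", "go_terms", "pathways", "xrefs",
)
IDENTIFIER_COLUMNS = ("token", "id_type", "entity_kind", "target_internal_id")
RELATION_COLUMNS = ("edge_id", "rel_type", "a", "b", "source_db", "method", "pubmed_ids")

MULTI_GENE_ALIAS = "multi-gene alias"
ALIAS_COLLIDES_WITH_SYMBOL = "alias-collides-with-symbol"


class DataStoreError(ValueError):
    """Raised for malformed or inconsistent datastore content.

    The message carries the file and line number when the problem is
    attributable to a specific row.
    """


@dataclass(frozen=True)
class BioEntity:
    internal_id: str
    kind: str
    organism: int
    primary_label: str
    description: str = ""
    go_terms: tuple[str, ...] = ()
    pathways: tuple[str, ...] = ()
    xrefs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise DataStoreError(
                f"entity {self.internal_id!r}: kind must be one of {ENTITY_KINDS}, got {self.kind!r}"
            )
        if not isinstance(self.organism, int) or self.organism <= 0:
            raise DataStoreError(
                f"entity {self.internal_id!r}: organism must be a positive taxon id, got {self.organism!r}"
            )


@dataclass(frozen=True)
class IdentifierRecord:
    token: str
    id_type: str
    entity_kind: str
    target: str

    def __post_init__(self) -> None:
        if self.id_type not in ID_TYPE_KIND:
            raise DataStoreError(f"unknown identifier type {self.id_type!r} for token {self.token!r}")
        expected = ID_TYPE_KIND[self.id_type]
        if self.entity_kind != expected:
            raise DataStoreError(
                f"token {self.token!r}: entity_kind {self.entity_kind!r} inconsistent with "
                f"id_type {self.id_type!r} (expected {expected!r})"
            )

    @property
    def lookup_key(self) -> str:
        return self.token.lower() if self.id_type in CASE_INSENSITIVE_ID_TYPES else self.token


@dataclass(frozen=True)
class Evidence:
    """Provenance of one supporting observation of a relation."""

    source_db: str
    method: str = ""
    pubmed_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.source_db:
            raise DataStoreError("evidence requires a non-empty source_db")


@dataclass(frozen=True)
class EvidenceEdge:
    """A typed relation with its full evidence list.

    Direction is meaningful for coding (a = gene, b = product) and pdna
    (a = protein, b = regulated gene); ppi is undirected and stored with
    endpoints in sorted order so each interaction has one canonical form.
    """

    edge_id: str
    rel_type: str
    a: str
    b: str
    evidence: tuple[Evidence, ...]

    def __post_init__(self) -> None:
        if self.rel_type not in REL_TYPES:
            raise DataStoreError(f"edge {self.edge_id!r}: unknown rel_type {self.rel_type!r}")
        if not self.evidence:
            raise DataStoreError(f"edge {self.edge_id!r}: evidence list must be non-empty")

    def other_endpoint(self, node: str) -> str:
        return self.b if node == self.a else self.a


class Resolution(NamedTuple):
    ids: frozenset[str]
    status: str  # resolved | unresolved | discarded


@dataclass
class TranslationTable:
    """Token -> entity lookup with ambiguity bookkeeping.

    ``resolved`` maps lookup keys (lower-cased for symbols/aliases, verbatim
    otherwise) to ``(internal_id, id_type)`` pairs; ``discarded`` maps the
    lookup key of each ambiguous alias token to the reason it was dropped.
    A token never appears in both.
    """

    resolved_exact: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    resolved_folded: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    discarded: dict[str, str] = field(default_factory=dict)
    n_records: int = 0
    n_discarded_records: int = 0
    entities: Mapping[str, BioEntity] = field(default_factory=dict)

    @property
    def resolved(self) -> dict[str, frozenset[tuple[str, str]]]:
        merged = dict(self.resolved_exact)
        for key, pairs in self.resolved_folded.items():
            merged[key] = merged.get(key, frozenset()) | pairs
        return merged

    def resolve(self, token: str, organism: int, kinds: Iterable[str]) -> Resolution:
        """Resolve one public token within an organism, restricted by kind.

        Exact-match identifier types (Uniprot, RefSeq, GenBank, UniGene,
        Entrez GeneID) are checked first; if the token matches none of them
        and its case-folded form was discarded as ambiguous, status is
        ``discarded``.  Otherwise candidates from case-insensitive types
        (symbols, aliases) are added, and the union is filtered by the
        requested organism and entity kinds.
        """
        kinds = frozenset(kinds)
        exact_hits = self.resolved_exact.get(token, frozenset())
        folded = token.lower()
        if not exact_hits and folded in self.discarded:
            return Resolution(frozenset(), "discarded")
        candidates = exact_hits | self.resolved_folded.get(folded, frozenset())
        ids = frozenset(
            target
            for target, _ in candidates
            if (ent := self.entities.get(target)) is not None
            and ent.organism == organism
            and ent.kind in kinds
        )
        return Resolution(ids, "resolved" if ids else "unresolved")


@dataclass
class DataStore:
    entities: dict[str, BioEntity]
    identifiers: list[IdentifierRecord]
    edges: list[EvidenceEdge]

    def entity(self, internal_id: str) -> BioEntity:
        try:
            return self.entities[internal_id]
        except KeyError:
            raise DataStoreError(f"unknown entity {internal_id!r}") from None


# ---------------------------------------------------------------------------
# TSV loading


def _read_rows(path: Path, columns: tuple[str, ...]):
    """Yield (line_number, row_dict) for a headered TSV, skipping # comments."""
    if not path.is_file():
        raise DataStoreError(f"{path}: file not found")
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                if tuple(header) != columns:
                    raise DataStoreError(
                        f"{path}:{lineno}: expected header {list(columns)}, got {header}"
                    )
                continue
            if len(row) != len(columns):
                raise DataStoreError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(row)}"
                )
            yield lineno, dict(zip(columns, row))
        if header is None:
            raise DataStoreError(f"{path}: missing header row")


def _split_pipe(value: str) -> tuple[str, ...]:
    return tuple(v for v in value.split("|") if v) if value else ()


def _load_entities(path: Path) -> dict[str, BioEntity]:
    entities: dict[str, BioEntity] = {}
    for lineno, row in _read_rows(path, ENTITY_COLUMNS):
        iid = row["internal_id"]
        if iid in entities:
            raise DataStoreError(f"{path}:{lineno}: duplicate internal_id {iid!r}")
        try:
            taxon = int(row["taxon"])
        except ValueError:
            raise DataStoreError(f"{path}:{lineno}: taxon must be an integer, got {row['taxon']!r}") from None
        xrefs = []
        for item in _split_pipe(row["xrefs"]):
            db, sep, acc = item.partition(":")
            if not sep or not db or not acc:
                raise DataStoreError(f"{path}:{lineno}: malformed xref {item!r} (want db:acc)")
            xrefs.append((db, acc))
        try:
            entities[iid] = BioEntity(
                internal_id=iid,
                kind=row["kind"],
                organism=taxon,
                primary_label=row["primary_label"],
                description=row["description"],
                go_terms=_split_pipe(row["go_terms"]),
                pathways=_split_pipe(row["pathways"]),
                xrefs=tuple(xrefs),
            )
        except DataStoreError as exc:
            raise DataStoreError(f"{path}:{lineno}: {exc}") from None
    return entities


def _load_identifiers(path: Path, entities: Mapping[str, BioEntity]) -> list[IdentifierRecord]:
    records: list[IdentifierRecord] = []
    for lineno, row in _read_rows(path, IDENTIFIER_COLUMNS):
        target = row["target_internal_id"]
        if target not in entities:
            raise DataStoreError(f"{path}:{lineno}: identifier target {target!r} is not a known entity")
        try:
            rec = IdentifierRecord(
                token=row["token"],
                id_type=row["id_type"],
                entity_kind=row["entity_kind"],
                target=target,
            )
        except DataStoreError as exc:
            raise DataStoreError(f"{path}:{lineno}: {exc}") from None
        expected = ID_TYPE_KIND[rec.id_type]
        actual = entities[target].kind
        if expected != "gene_or_protein" and actual != expected:
            raise DataStoreError(
                f"{path}:{lineno}: token {rec.token!r} of type {rec.id_type!r} targets a {actual}"
            )
        records.append(rec)
    return records


def _load_relations(path: Path, entities: Mapping[str, BioEntity]) -> list[EvidenceEdge]:
    # One row per evidence item; rows sharing an edge_id must agree on the
    # relation, and edges from different sources describing the same
    # relation are merged into one EvidenceEdge.
    raw: dict[str, dict] = {}
    for lineno, row in _read_rows(path, RELATION_COLUMNS):
        eid, rel, a, b = row["edge_id"], row["rel_type"], row["a"], row["b"]
        for endpoint in (a, b):
            if endpoint not in entities:
                raise DataStoreError(
                    f"{path}:{lineno}: edge {eid!r} references unknown entity {endpoint!r}"
                )
        if rel not in REL_TYPES:
            raise DataStoreError(f"{path}:{lineno}: edge {eid!r} has unknown rel_type {rel!r}")
        ka, kb = entities[a].kind, entities[b].kind
        want = {CODING: (GENE, PROTEIN), PPI: (PROTEIN, PROTEIN), PDNA: (PROTEIN, GENE)}[rel]
        if (ka, kb) != want:
            raise DataStoreError(
                f"{path}:{lineno}: edge {eid!r} ({rel}) requires endpoint kinds {want}, got ({ka}, {kb})"
            )
        try:
            pubmed = tuple(int(p) for p in _split_pipe(row["pubmed_ids"]))
        except ValueError:
            raise DataStoreError(f"{path}:{lineno}: non-integer PubMed id in {row['pubmed_ids']!r}") from None
        if not row["source_db"]:
            raise DataStoreError(f"{path}:{lineno}: edge {eid!r} has empty source_db")
        ev = Evidence(source_db=row["source_db"], method=row["method"], pubmed_ids=pubmed)
        if rel == PPI and a > b:
            a, b = b, a
        entry = raw.setdefault(eid, {"rel_type": rel, "a": a, "b": b, "evidence": []})
        if (entry["rel_type"], entry["a"], entry["b"]) != (rel, a, b):
            raise DataStoreError(
                f"{path}:{lineno}: edge {eid!r} redefined with conflicting relation"
            )
        entry["evidence"].append(ev)

    # merge distinct edge_ids describing the same (rel_type, a, b)
    merged: dict[tuple[str, str, str], dict] = {}
    for eid in sorted(raw):
        entry = raw[eid]
        key = (entry["rel_type"], entry["a"], entry["b"])
        tgt = merged.setdefault(key, {"edge_id": eid, "evidence": []})
        tgt["edge_id"] = min(tgt["edge_id"], eid)
        tgt["evidence"].extend(entry["evidence"])

    edges = []
    for (rel, a, b), entry in merged.items():
        evidence = tuple(sorted(set(entry["evidence"]),
                                key=lambda e: (e.source_db, e.method, e.pubmed_ids)))
        edges.append(EvidenceEdge(entry["edge_id"], rel, a, b, evidence))
    edges.sort(key=lambda e: e.edge_id)
    return edges


def load_datastore(
    directory: str | Path | None = None,
    *,
    entities_path: str | Path | None = None,
    identifiers_path: str | Path | None = None,
    relations_path: str | Path | None = None,
) -> DataStore:
    """Load and validate a datastore from its three TSV files.

    Either point ``directory`` at a folder containing ``entities.tsv``,
    ``identifiers.tsv`` and ``relations.tsv``, or pass the three paths
    explicitly.  Every invariant (unique internal ids, endpoint kinds per
    relation type, resolvable targets) is enforced at load time; violations
    raise :class:`DataStoreError` naming the file and line.
    """
    if directory is not None:
        directory = Path(directory)
        entities_path = entities_path or directory / "entities.tsv"
        identifiers_path = identifiers_path or directory / "identifiers.tsv"
        relations_path = relations_path or directory / "relations.tsv"
    if not (entities_path and identifiers_path and relations_path):
        raise DataStoreError("load_datastore needs a directory or all three file paths")
    entities = _load_entities(Path(entities_path))
    identifiers = _load_identifiers(Path(identifiers_path), entities)
    edges = _load_relations(Path(relations_path), entities)
    return DataStore(entities=entities, identifiers=identifiers, edges=edges)


# ---------------------------------------------------------------------------
# Translation table


def build_translation_table(
    records: Iterable[IdentifierRecord],
    entities: Mapping[str, BioEntity],
) -> TranslationTable:
    """Build the disambiguated token -> entity translation table.

    Gene aliases are the only identifier class with cross-namespace
    collisions.  An alias is discarded when it names more than one distinct
    gene, or when it equals (case-insensitively) the official symbol of a
    different gene; discarding removes the token from identification
    entirely.  For every other identifier type, duplicate tokens pointing at
    different targets of the same kind and organism indicate a corrupt
    store and are fatal.
    """
    records = list(records)
    for rec in records:
        if rec.target not in entities:
            raise DataStoreError(f"identifier {rec.token!r} targets unknown entity {rec.target!r}")

    # corrupt-store check for non-alias types
    seen: dict[tuple[str, str, str, int], str] = {}
    for rec in records:
        if rec.id_type == "gene_alias":
            continue
        ent = entities[rec.target]
        key = (rec.lookup_key, rec.id_type, ent.kind, ent.organism)
        prior = seen.setdefault(key, rec.target)
        if prior != rec.target:
            raise DataStoreError(
                f"corrupt store: token {rec.token!r} ({rec.id_type}) maps to both "
                f"{prior!r} and {rec.target!r}"
            )

    alias_targets: dict[str, set[str]] = {}
    symbol_targets: dict[str, set[str]] = {}
    for rec in records:
        if rec.id_type == "gene_alias":
            alias_targets.setdefault(rec.lookup_key, set()).add(rec.target)
        elif rec.id_type == "entrez_symbol":
            symbol_targets.setdefault(rec.lookup_key, set()).add(rec.target)

    discarded: dict[str, str] = {}
    for key, genes in sorted(alias_targets.items()):
        if len(genes) > 1:
            discarded[key] = MULTI_GENE_ALIAS
        elif symbol_targets.get(key, set()) - genes:
            discarded[key] = ALIAS_COLLIDES_WITH_SYMBOL

    exact: dict[str, set[tuple[str, str]]] = {}
    folded: dict[str, set[tuple[str, str]]] = {}
    n_discarded_records = 0
    for rec in records:
        if rec.id_type in CASE_INSENSITIVE_ID_TYPES:
            if rec.lookup_key in discarded:
                n_discarded_records += 1
                continue
            folded.setdefault(rec.lookup_key, set()).add((rec.target, rec.id_type))
        else:
            exact.setdefault(rec.lookup_key, set()).add((rec.target, rec.id_type))

    return TranslationTable(
        resolved_exact={k: frozenset(v) for k, v in exact.items()},
        resolved_folded={k: frozenset(v) for k, v in folded.items()},
        discarded=discarded,
        n_records=len(records),
        n_discarded_records=n_discarded_records,
        entities=dict(entities),
    )


def resolve(token: str, organism: int, kinds: Iterable[str], table: TranslationTable) -> Resolution:
    """Functional form of :meth:`TranslationTable.resolve`."""
    return table.resolve(token, organism, kinds)
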