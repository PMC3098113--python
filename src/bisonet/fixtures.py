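"""Synthetic datastore generators.

``make_worked_examples`` emits a small, fully hand-specified human store
whose neighborhoods reproduce the tool's canonical demonstrations:

* a CPM neighborhood where distance-1 gene-level expansion from the CPM
  seed yields exactly the four genes CPM, HBA1, HBA2 and EGF;
* an HBA1/HBA2 cluster with exactly five interactors that share the open
  neighborhood {HBA1, HBA2}, surfacing as one five-member equivalent set
  after the network is expanded from the added nodes;
* an HLA-A-like gene with three splice-variant products (1A02_HUMAN
  carrying the most interactions) and a ubiquitin-like protein coded by
  two different genes — the coding-distance-zero showcases;
* identifier records covering every supported identifier type, including
  one multi-gene alias (VH) and one alias colliding with another gene's
  official symbol, both of which the translation table must discard.

The interaction content is synthetic: it is shaped to the published
figure descriptions, not copied from any database release.

``make_random_store`` emits seeded random stores of tunable size with a
manifest of exact ground-truth counts, for property tests against
independent oracles.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .datastore import (
    CODING,
    ENTITY_COLUMNS,
    IDENTIFIER_COLUMNS,
    PDNA,
    PPI,
    RELATION_COLUMNS,
)

__all__ = ["make_worked_examples", "make_random_store"]

HUMAN = 9606
MOUSE = 10090


def _write_tsv(path: Path, columns: Sequence[str], rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _merged_edge_count(rows: Sequence[Sequence]) -> dict[str, int]:
    seen: dict[str, set[tuple[str, str, str]]] = {CODING: set(), PPI: set(), PDNA: set()}
    for row in rows:
        rel, a, b = row[1], row[2], row[3]
        if rel == PPI and a > b:
            a, b = b, a
        seen[rel].add((rel, a, b))
    return {rel: len(keys) for rel, keys in seen.items()}


def _emit(out_dir: Path, entities, identifiers, relations, manifest: dict) -> dict:
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write-probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from None
    _write_tsv(out_dir / "entities.tsv", ENTITY_COLUMNS, entities)
    _write_tsv(out_dir / "identifiers.tsv", IDENTIFIER_COLUMNS, identifiers)
    _write_tsv(out_dir / "relations.tsv", RELATION_COLUMNS, relations)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# worked examples


def make_worked_examples(out_dir: str | Path) -> dict:
    """Write the worked-example store and return its manifest."""

    genes = [
        # internal_id, symbol, entrez geneid, taxon, description
        ("G_CPM", "CPM", 1368, HUMAN, "carboxypeptidase M"),
        ("G_HBA1", "HBA1", 3039, HUMAN, "hemoglobin subunit alpha 1"),
        ("G_HBA2", "HBA2", 3040, HUMAN, "hemoglobin subunit alpha 2"),
        ("G_EGF", "EGF", 1950, HUMAN, "epidermal growth factor"),
        ("G_EGFR", "EGFR", 1956, HUMAN, "epidermal growth factor receptor"),
        ("G_AHSP", "AHSP", 51327, HUMAN, "alpha hemoglobin stabilizing protein"),
        ("G_HP", "HP", 3240, HUMAN, "haptoglobin"),
        ("G_HPX", "HPX", 3263, HUMAN, "hemopexin"),
        ("G_HEMGN", "HEMGN", 55363, HUMAN, "hemogen"),
        ("G_FECH", "FECH", 2235, HUMAN, "ferrochelatase"),
        ("G_HLA_A", "HLA-A", 3105, HUMAN, "major histocompatibility complex, class I, A"),
        ("G_B2M", "B2M", 567, HUMAN, "beta-2-microglobulin"),
        ("G_UBB", "UBB", 7314, HUMAN, "ubiquitin B"),
        ("G_UBC", "UBC", 7316, HUMAN, "ubiquitin C"),
        ("G_GATA1", "GATA1", 2623, HUMAN, "GATA binding protein 1 (erythroid)"),
        ("G_AMBX", "AMBX", 990001, HUMAN, "synthetic ambiguity-test gene X"),
        ("G_AMBY", "AMBY", 990002, HUMAN, "synthetic ambiguity-test gene Y"),
        ("G_TRP53M", "Trp53", 22059, MOUSE, "transformation related protein 53 (mouse)"),
    ]
    proteins = [
        # internal_id, uniprot id label, uniprot accession, taxon, coding genes
        ("P_CPM", "CBPM_HUMAN", "P14384", HUMAN, ["G_CPM"]),
        ("P_HBA1", "HBA1_HUMAN", "P69901", HUMAN, ["G_HBA1"]),
        ("P_HBA2", "HBA2_HUMAN", "P69902", HUMAN, ["G_HBA2"]),
        ("P_EGF", "EGF_HUMAN", "P01133", HUMAN, ["G_EGF"]),
        ("P_EGFR", "EGFR_HUMAN", "P00533", HUMAN, ["G_EGFR"]),
        ("P_AHSP", "AHSP_HUMAN", "Q9NZD4", HUMAN, ["G_AHSP"]),
        ("P_HP", "HPT_HUMAN", "P00738", HUMAN, ["G_HP"]),
        ("P_HPX", "HEMO_HUMAN", "P02790", HUMAN, ["G_HPX"]),
        ("P_HEMGN", "HEMGN_HUMAN", "Q9BXL5", HUMAN, ["G_HEMGN"]),
        ("P_FECH", "HEMH_HUMAN", "P22830", HUMAN, ["G_FECH"]),
        ("P_1A01", "1A01_HUMAN", "P30443", HUMAN, ["G_HLA_A"]),
        ("P_1A02", "1A02_HUMAN", "P01892", HUMAN, ["G_HLA_A"]),
        ("P_1A03", "1A03_HUMAN", "P04439", HUMAN, ["G_HLA_A"]),
        ("P_B2M", "B2MG_HUMAN", "P61769", HUMAN, ["G_B2M"]),
        ("P_UBIQ", "UBIQ_HUMAN", "P0CG47", HUMAN, ["G_UBB", "G_UBC"]),
        ("P_GATA1", "GATA1_HUMAN", "P15976", HUMAN, ["G_GATA1"]),
        ("P_AMBX", "AMBX_SYNT", "P99001", HUMAN, ["G_AMBX"]),
        ("P_AMBY", "AMBY_SYNT", "P99002", HUMAN, ["G_AMBY"]),
        ("P_TRP53M", "P53_MOUSE", "P02340", MOUSE, ["G_TRP53M"]),
    ]

    go = {
        "G_CPM": "GO:0004181|GO:0005886",
        "G_HBA1": "GO:0005344|GO:0019825",
        "G_HBA2": "GO:0005344|GO:0019825",
        "G_EGF": "GO:0005154|GO:0008083",
        "G_HLA_A": "GO:0002474",
        "P_UBIQ": "GO:0031386",
    }
    pathways = {
        "G_EGF": "hsa04010|hsa04012",
        "G_EGFR": "hsa04010|hsa04012",
        "G_HLA_A": "hsa04612",
        "G_B2M": "hsa04612",
    }

    entities = []
    for iid, symbol, geneid, taxon, desc in genes:
        entities.append(
            (iid, "gene", taxon, symbol, desc, go.get(iid, ""), pathways.get(iid, ""),
             f"EntrezGene:{geneid}")
        )
    for iid, label, acc, taxon, _coders in proteins:
        entities.append(
            (iid, "protein", taxon, label, f"product {label}", go.get(iid, ""),
             pathways.get(iid, ""), f"Uniprot:{acc}")
        )

    identifiers = []
    for iid, symbol, geneid, _taxon, _desc in genes:
        identifiers.append((symbol, "entrez_symbol", "gene", iid))
        identifiers.append((geneid, "entrez_geneid", "gene", iid))
    for iid, label, acc, _taxon, _coders in proteins:
        identifiers.append((label, "uniprot_id", "protein", iid))
        identifiers.append((acc, "uniprot_accession", "protein", iid))
    identifiers += [
        ("NM_001963", "refseq_accession", "gene", "G_EGF"),
        ("NP_001954", "refseq_protein_id", "gene_or_protein", "G_EGF"),
        ("NP_001954", "refseq_protein_id", "gene_or_protein", "P_EGF"),
        ("Hs.419815", "unigene_cluster", "gene", "G_EGF"),
        ("X04571", "genbank_accession", "gene", "G_EGF"),
        ("CAA28240", "genbank_protein_accession", "gene", "G_EGF"),
        ("Q52LZ6", "uniprot_secondary_accession", "protein", "P_EGF"),
        ("URG", "gene_alias", "gene", "G_EGF"),
        ("HOMG4", "gene_alias", "gene", "G_EGF"),
        # alias equal to the gene's own symbol: no ambiguity, stays resolved
        ("HP", "gene_alias", "gene", "G_HP"),
        # multi-gene alias: must be discarded
        ("VH", "gene_alias", "gene", "G_AMBX"),
        ("VH", "gene_alias", "gene", "G_AMBY"),
        ("VH", "gene_alias", "gene", "G_EGFR"),
        # alias colliding with a different gene's official symbol
        ("AMBX", "gene_alias", "gene", "G_AMBY"),
    ]

    relations = []
    cix = 0
    for iid, _label, _acc, _taxon, coders in proteins:
        for gene in coders:
            cix += 1
            relations.append(
                (f"C{cix:03d}", CODING, gene, iid, "EntrezGene", "curated coding annotation", "")
            )

    ppi = [
        # a, b, [(source, method, pubmed), ...]
        ("P_CPM", "P_HBA1", [("HPRD", "two hybrid", "11283024"),
                             ("BioGRID", "affinity chromatography technology", "14702039")]),
        ("P_CPM", "P_HBA2", [("HPRD", "two hybrid", "11283024")]),
        ("P_CPM", "P_EGF", [("DIP", "two hybrid", "10748158")]),
        ("P_HBA1", "P_HBA2", [("IntAct", "x-ray crystallography", "6726807")]),
        ("P_AHSP", "P_HBA1", [("BIND", "anti tag coimmunoprecipitation", "12032088")]),
        ("P_AHSP", "P_HBA2", [("BIND", "anti tag coimmunoprecipitation", "12032088")]),
        ("P_HP", "P_HBA1", [("MINT", "affinity chromatography technology", "16169070")]),
        ("P_HP", "P_HBA2", [("MINT", "affinity chromatography technology", "16169070")]),
        ("P_HPX", "P_HBA1", [("HPRD", "two hybrid", "16169071")]),
        ("P_HPX", "P_HBA2", [("HPRD", "two hybrid", "16169071")]),
        ("P_HEMGN", "P_HBA1", [("BioGRID", "two hybrid", "16169072")]),
        ("P_HEMGN", "P_HBA2", [("BioGRID", "two hybrid", "16169072")]),
        ("P_FECH", "P_HBA1", [("IntAct", "two hybrid", "16169073")]),
        ("P_FECH", "P_HBA2", [("IntAct", "two hybrid", "16169073")]),
        ("P_EGF", "P_EGFR", [("DIP", "x-ray crystallography", "12297050"),
                             ("HPRD", "anti tag coimmunoprecipitation", "7679104")]),
        ("P_EGFR", "P_EGFR", [("BioGRID", "two hybrid", "16777603")]),  # homodimer loop
        ("P_1A01", "P_B2M", [("IntAct", "x-ray crystallography", "2784196")]),
        ("P_1A02", "P_B2M", [("IntAct", "x-ray crystallography", "3309677")]),
        ("P_1A02", "P_UBIQ", [("BioGRID", "affinity chromatography technology", "17139261")]),
        ("P_AMBX", "P_AMBY", [("DIP", "two hybrid", "19000000")]),
    ]
    pix = 0
    for a, b, evidence in ppi:
        pix += 1
        for source, method, pubmed in evidence:
            relations.append((f"I{pix:03d}", PPI, a, b, source, method, pubmed))
    # same interaction reported under a second edge id: the loader must merge
    relations.append(("I901", PPI, "P_HBA1", "P_CPM", "MINT",
                      "affinity chromatography technology", "15231748"))

    relations.append(("D001", PDNA, "P_GATA1", "G_HBA1", "IntAct",
                      "chromatin immunoprecipitation", "1985916"))

    counts = _merged_edge_count(relations)
    manifest = {
        "preset": "worked-examples",
        "seed": None,
        "counts": {
            "genes": len(genes),
            "proteins": len(proteins),
            "entities": len(entities),
            "coding_edges": counts[CODING],
            "ppi_edges": counts[PPI],
            "pdna_edges": counts[PDNA],
            "identifier_records": len(identifiers),
        },
        "expectations": {
            "cpm_seed_token": "CPM",
            "cpm_distance1_gene_count": 4,
            "cpm_distance1_gene_labels": ["CPM", "EGF", "HBA1", "HBA2"],
            "expand_selection_labels": ["EGF", "HBA1", "HBA2"],
            "equivalent_set_size": 5,
            "equivalent_member_labels": ["AHSP", "FECH", "HEMGN", "HP", "HPX"],
            "equivalent_shared_labels": ["HBA1", "HBA2"],
            "hla_seed_token": "hla-a",
            "hla_isoform_count": 3,
            "hla_isoform_with_most_ppi": "1A02_HUMAN",
            "multi_gene_protein": "UBIQ_HUMAN",
            "multi_gene_protein_coding_genes": 2,
            "discarded_tokens": {
                "vh": "multi-gene alias",
                "ambx": "alias-collides-with-symbol",
            },
        },
    }
    return _emit(Path(out_dir), entities, identifiers, relations, manifest)


# ---------------------------------------------------------------------------
# random stores


_SOURCE_POOL = ["DIP", "BIND", "HPRD", "MINT", "IntAct", "BioGRID",
                "SRC07", "SRC08", "SRC09", "SRC10"]
_METHOD_POOL = ["two hybrid", "anti tag coimmunoprecipitation",
                "affinity chromatography technology", "x-ray crystallography"]


def make_random_store(
    out_dir: str | Path,
    *,
    seed: int,
    n_genes: int = 50,
    isoform_probs: Sequence[float] = (0.8, 0.15, 0.05),
    ppi_density: float = 0.02,
    pdna_density: float = 0.005,
    alias_ambiguity_rate: float = 0.05,
    n_sources: int = 4,
    taxon: int = HUMAN,
) -> dict:
    """Write a seeded random store; byte-identical for a given seed.

    ``isoform_probs[k]`` is the probability that a gene has k+1 protein
    products, so every protein has at least one coding gene by
    construction.  PPIs are Bernoulli over unordered protein pairs and
    protein–DNA edges Bernoulli over (protein, gene) pairs.  A fraction
    ``alias_ambiguity_rate`` of genes contributes deliberately shared
    aliases, listed in the manifest for disambiguation tests.
    """
    if not isinstance(seed, (int, np.integer)):
        raise ValueError("parameter 'seed' must be an integer")
    if n_genes < 1:
        raise ValueError("parameter 'n_genes' must be >= 1")
    probs = np.asarray(isoform_probs, dtype=float)
    if probs.ndim != 1 or len(probs) == 0 or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("parameter 'isoform_probs' must be non-negative and sum to 1")
    for name, value in (("ppi_density", ppi_density), ("pdna_density", pdna_density),
                        ("alias_ambiguity_rate", alias_ambiguity_rate)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"parameter {name!r} must be in [0, 1]")
    if not 1 <= n_sources <= len(_SOURCE_POOL):
        raise ValueError(f"parameter 'n_sources' must be in [1, {len(_SOURCE_POOL)}]")

    rng = np.random.default_rng(seed)
    sources = _SOURCE_POOL[:n_sources]

    entities = []
    identifiers = []
    gene_ids = []
    protein_ids = []
    coding_rows = []
    pix = 0
    for i in range(1, n_genes + 1):
        gid = f"G{i:04d}"
        symbol = f"GEN{i:04d}"
        gene_ids.append(gid)
        entities.append((gid, "gene", taxon, symbol, f"synthetic gene {i}",
                         f"GO:{7000000 + i}", "", f"EntrezGene:{100000 + i}"))
        identifiers.append((symbol, "entrez_symbol", "gene", gid))
        identifiers.append((100000 + i, "entrez_geneid", "gene", gid))
        identifiers.append((f"AL_{symbol}", "gene_alias", "gene", gid))
        n_isoforms = int(rng.choice(len(probs), p=probs)) + 1
        for _ in range(n_isoforms):
            pix += 1
            piid = f"P{pix:04d}"
            label = f"PR{pix:04d}_SYN"
            protein_ids.append(piid)
            entities.append((piid, "protein", taxon, label, f"synthetic protein {pix}",
                             "", "", f"Uniprot:Q{90000 + pix}"))
            identifiers.append((label, "uniprot_id", "protein", piid))
            identifiers.append((f"Q{90000 + pix}", "uniprot_accession", "protein", piid))
            coding_rows.append((f"C{pix:04d}", CODING, gid, piid,
                                "EntrezGene", "curated coding annotation", ""))

    ambiguous: dict[str, list[str]] = {}
    n_ambiguous = int(round(alias_ambiguity_rate * n_genes))
    for j in range(n_ambiguous):
        token = f"AMB{j:03d}"
        k = int(rng.integers(2, min(4, n_genes) + 1)) if n_genes >= 2 else 2
        picks = sorted(rng.choice(len(gene_ids), size=min(k, len(gene_ids)), replace=False))
        targets = [gene_ids[p] for p in picks]
        if len(targets) < 2:
            continue
        ambiguous[token.lower()] = targets
        for gid in targets:
            identifiers.append((token, "gene_alias", "gene", gid))

    relations = list(coding_rows)
    eix = 0

    def evidence_rows(edge_id: str, rel: str, a: str, b: str):
        n_ev = 1 + int(rng.random() < 0.3)
        picked = rng.choice(len(sources), size=min(n_ev, len(sources)), replace=False)
        rows = []
        for s in picked:
            method = _METHOD_POOL[int(rng.integers(len(_METHOD_POOL)))]
            pubmed = "|".join(
                str(int(rng.integers(10_000_000, 30_000_000)))
                for _ in range(1 + int(rng.random() < 0.4))
            )
            rows.append((edge_id, rel, a, b, sources[int(s)], method, pubmed))
        return rows

    for i in range(len(protein_ids)):
        for j in range(i, len(protein_ids)):
            # includes i == j: rare self-interaction loops
            p = ppi_density * (0.1 if i == j else 1.0)
            if rng.random() < p:
                eix += 1
                relations += evidence_rows(f"I{eix:05d}", PPI, protein_ids[i], protein_ids[j])
    dix = 0
    for piid in protein_ids:
        for gid in gene_ids:
            if rng.random() < pdna_density:
                dix += 1
                relations += evidence_rows(f"D{dix:05d}", PDNA, piid, gid)

    counts = _merged_edge_count(relations)
    manifest = {
        "preset": "random",
        "seed": int(seed),
        "parameters": {
            "n_genes": n_genes,
            "isoform_probs": [float(p) for p in probs],
            "ppi_density": ppi_density,
            "pdna_density": pdna_density,
            "alias_ambiguity_rate": alias_ambiguity_rate,
            "n_sources": n_sources,
            "taxon": taxon,
        },
        "counts": {
            "genes": len(gene_ids),
            "proteins": len(protein_ids),
            "entities": len(entities),
            "coding_edges": counts[CODING],
            "ppi_edges": counts[PPI],
            "pdna_edges": counts[PDNA],
            "identifier_records": len(identifiers),
        },
        "ambiguous_aliases": {k: v for k, v in sorted(ambiguous.items())},
    }
    return _emit(Path(out_dir), entities, identifiers, relations, manifest)
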