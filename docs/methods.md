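# Methods

## The model

`bisonet` builds interaction networks over a typed graph of molecular
entities in which genes and their protein products are distinct nodes.
Three relation types connect them:

* **coding** — directed gene → protein edge for each product (splice
  variant) of the gene; a protein coded by several genes carries several
  incoming coding edges;
* **ppi** — undirected protein–protein interaction;
* **pdna** — directed protein → gene edge for a protein (typically a
  transcription factor) binding the gene's promoter region.

Every edge carries a non-empty evidence list: one or more observations,
each with a source database name, a free-text experimental-method label
and supporting PubMed ids.  Method labels are kept exactly as the source
provides them; no controlled vocabulary is imposed.

### Distance semantics

The defining convention is that **coding edges have length 0** while ppi
and pdna edges have length 1.  Distances are weighted shortest-path
lengths under that assignment.  The consequence is that a gene and all of
its products always sit at the same distance from any seed set: a
distance-1 query from a gene returns the interaction partners of its
products *and* those partners' genes, and a distance-0 query from a
multi-isoform gene already contains every splice variant.

Expansion is computed by a multi-source 0-1 BFS (deque-based: zero-length
relaxations go to the front), which is exact for {0,1} weights and linear
in the subgraph explored.  The test suite cross-checks the resulting node
sets against an independent weighted-Dijkstra implementation built
directly from the raw relation table.

All edge types are traversable in both directions during expansion.  For
coding edges this is forced (building outward from a gene must cross its
own coding edge from the gene side); for pdna edges it is a design
choice — a gene already in the network pulls in the proteins regulating
it — and the stored direction is preserved as an edge attribute for
rendering and export.

### Network construction

A build request (`NetworkQuery`) fixes the organism, the entity kinds
used for token identification, an edge filter, the inclusion radius N and
the output representation.  Construction has three stages:

1. **identify** — every input token is resolved through the translation
   table, restricted to the query's organism and kinds.  Tokens that
   resolve to nothing are reported with a status (`unresolved` or
   `discarded`) but never abort the build; only an entirely empty seed
   set is fatal.
2. **expand** — 0-1 BFS from the seed set to all nodes within distance N,
   over edges surviving the filter; the edge set of the result is the
   **induced** one (every surviving edge with both endpoints included),
   so seeds adjacent in the supergraph come out interconnected rather
   than joined only by traversal-tree edges.
3. **project** — see below.

Edge filtering is evidence-aware with *any* semantics: an edge survives
if its relation type is allowed and at least one evidence item passes
both the source and the method restriction.  An empty source or method
set means no restriction.  Any-semantics keeps maximal recall when an
edge has mixed provenance, which suits the exploratory use of the tool;
the alternative (all-evidence) would silently drop multiply-reported
edges whenever one source is deselected.

### Projections

* **genes and proteins with coding** — the subgraph passes through
  unchanged; coding edges carry a `dashed` attribute as the conventional
  render hint (dashed arrow from gene to product).
* **genes only** — each protein is contracted into the gene(s) coding
  it.  A ppi (p1, p2) becomes a gene–gene edge for every coding pair; a
  pdna (p, g) becomes (gene(p), g).  Evidence is preserved and merged
  when parallel projected edges collapse; edges that contract into a
  single gene (interactions between isoforms of one gene) are dropped.
  Proteins with no coding gene anywhere in the store are dropped with a
  warning.
* **proteins only** — gene nodes are dropped, ppi edges kept, and each
  pdna edge is re-attached from the regulator protein to every product of
  the regulated gene present in the subgraph; coding edges disappear.

Contraction uses the store's full coding relation, not the
filter-restricted one: projection is a change of representation, while
the filter governs which interactions are explored.  When coding edges do
pass the filter the two views coincide, because a protein's genes are
included at the protein's own distance.

Seed flags lift across coding edges during projection (a seed protein
marks its gene in the gene view and vice versa), and distances contract
by minimum.

### Identifier resolution and disambiguation

Supported identifier types: Entrez official symbol, Entrez GeneID, RefSeq
accession, RefSeq protein id, gene alias, UniGene cluster, GenBank
(nucleotide and protein) accession, Uniprot id/accession/secondary
accession.  RefSeq protein ids may name the gene, the protein or both,
decided by the query's requested kinds.  GenBank protein accessions are
typed as *gene* identifiers in the supported-identifier catalogue and are
resolved to the gene record accordingly.

Symbols and aliases match case-insensitively (their capitalization varies
across sources); accession-style identifiers match exactly.  Resolution
is scoped to a single organism chosen in the query; cross-organism lookup
is out of scope.

Gene aliases are the one identifier class with real ambiguity.  The
translation table discards an alias token when it

* names more than one distinct gene (*multi-gene alias*), or
* equals, case-insensitively, the official symbol of a different gene
  (*alias-collides-with-symbol*).

Discarding removes the token from identification entirely — in the
collision case including the symbol record itself, so that `resolved` and
`discarded` partition the token space and a discarded token has one
unambiguous status.  The affected genes remain reachable through their
other identifiers (every entity carries at least one unambiguous id).
An alias equal to its *own* gene's symbol carries no ambiguity and stays
resolved; this case is an interpretation, as is the wholesale-discard
reading of the collision rule.  Duplicate non-alias tokens pointing at
different targets of the same kind and organism indicate a corrupt store
and are fatal.

### Analyses

* **Equivalent nodes** — nodes with identical *open* neighborhoods
  (the node itself excluded from its signature) are grouped; classes of
  size ≥ 2 are reported with their shared neighbor set, largest first.
  Open-neighborhood equality means two adjacent nodes are equivalent only
  if each lies in the other's signature; the closed-neighborhood
  alternative would also merge adjacent twins, and is not used.  Isolated
  nodes share the empty neighborhood and group together.  Parallel edges
  are collapsed and self-loops ignored for signatures.
* **Shortest paths** — all pairs among a selected subset, under the same
  0/1 length convention (an `imported` edge costs 1).  Ties between
  shortest paths are broken by lexicographically smallest node sequence,
  computed by a Dijkstra variant whose priority is the (length, path)
  pair, making reports reproducible.  Unreachable pairs get infinite
  length.
* **Topology statistics** — degree (distinct neighbors on the collapsed
  graph, a self-loop counting once), degree histogram, and the local
  clustering coefficient C(v) = 2·t(v) / (k(v)·(k(v)−1)) with t(v) the
  triangle count through v, defined as 0 for k < 2; self-loops are
  excluded from triangle counting.  The mean averages over all nodes.

## Synthetic data

The package is testable entirely on generated stores; nothing is
downloaded.

`make_worked_examples` emits a fully hand-specified human store (37
entities) whose neighborhoods realize the canonical demonstrations: a CPM
neighborhood whose distance-1 gene-level network is exactly {CPM, HBA1,
HBA2, EGF}; five genes (AHSP, HP, HPX, HEMGN, FECH) whose products
interact with exactly the two hemoglobin-alpha products, forming one
five-member equivalence set with shared neighborhood {HBA1, HBA2} after
the network is expanded from the added nodes; an HLA-A gene with three
splice-variant products of which 1A02_HUMAN carries the most
interactions; a ubiquitin-like protein coded by both UBB and UBC; a GATA1
protein–DNA edge into HBA1; one EGFR homodimer self-interaction; one
identifier record of every supported type; and deliberately ambiguous
aliases (a multi-gene alias and an alias colliding with another gene's
symbol).  The interaction content is shaped to these structural
requirements, not copied from any database release — the store is a
structural template of the published neighborhoods, not a snapshot.  A
mouse gene is included to exercise organism scoping.

`make_random_store` generates seeded random stores: each gene receives
1–k products with probabilities `isoform_probs` (default (0.8, 0.15,
0.05) — mostly single-product genes, occasional isoforms), ppi edges are
Bernoulli over unordered protein pairs (`ppi_density`, default 0.02,
self-interactions at a tenth of that rate), pdna edges Bernoulli over
(protein, gene) pairs (default 0.005), and evidence is drawn from
`n_sources` database names and four method labels with 1–2 items per
edge.  A fraction `alias_ambiguity_rate` of genes contributes shared
aliases, listed in the manifest so disambiguation can be checked exactly.
Output is byte-deterministic per seed, and the manifest records exact
post-merge edge counts.

What the generator does **not** emulate: scale-free degree structure,
correlated evidence between databases, organism mixtures within one
store, or biologically meaningful annotation.  Passing tests therefore
demonstrate the correctness of the graph machinery — resolution,
expansion, projection, analysis, serialization — on stores with the right
*shape*, not performance or recall on real database content.

## Numerical and procedural choices

* Relation rows sharing an edge id, and distinct edge ids describing the
  same (rel_type, endpoints), merge into one edge; ppi endpoints are
  canonically sorted; the merged edge keeps the lexicographically
  smallest id and a de-duplicated, sorted evidence list.  Loading the
  same files twice yields identical stores.
* Self-interactions (homodimers) are legal ppi loops.
* Neighbor lists, equivalence sets, path witnesses and serialized
  documents are all deterministically ordered; XML serialization is
  byte-identical across calls (gzip written without timestamp).
* Property-test problem sizes: the oracle sweeps use 100 random stores of
  8–25 genes each, which already cover every structural case (isoforms,
  loops, multi-evidence edges, ambiguous aliases) while keeping the whole
  suite around two seconds.
* In external-network conversion, a name resolving to both a gene and a
  protein is mapped to the lexicographically smallest internal id for
  determinism; imported edges with no store counterpart get type
  `imported` rather than a guessed `ppi`, since external semantics are
  unknown.

## Known limitations

* No incremental store updates: the supergraph is rebuilt from the TSV
  files each run (assembly is linear and fast at desk scale).
* Gene-level projection can add coding genes that were outside the
  expanded subgraph when coding edges were excluded from the filter; they
  enter at their product's distance.
* microRNA relations, pathway-diagram output and hypergraph
  representations are out of scope.
* The translation table resides in memory; stores far beyond desk scale
  would need an indexed backend.
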