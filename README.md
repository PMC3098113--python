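# bisonet

Seed-based construction and analysis of gene/protein interaction
networks with explicit coding relations.

Most network tools collapse a gene and its protein products into a single
node, so regulatory and physical interactions that belong to different
molecules get painted onto the same dot.  `bisonet` keeps them apart: a
gene is connected to each of its products (splice variants included) by a
directed **coding** edge, proteins interact through undirected **ppi**
edges, and transcription factors point at the genes they regulate through
**pdna** edges.  Coding edges are assigned **distance zero**, so a gene
and its products are interchangeable as far as network distance is
concerned — expanding one step from a gene reaches the interaction
partners of its products — while remaining distinct, inspectable nodes.
That makes it possible to represent isoform-specific interactions and
proteins shared by several genes, which a merged representation cannot.

It is aimed at anyone turning a list of identifiers from a genomics or
proteomics experiment into an annotated functional network: the input is
a handful of gene symbols or accessions, the output a network whose nodes
carry descriptions, GO terms and pathway ids, and whose edges carry
source databases, experimental methods and PubMed references.

## The model in brief

Let G be the multigraph over all genes and proteins in the datastore with
edge lengths ℓ(e) = 0 for coding edges and 1 otherwise.  Given seed nodes
S (resolved from the user's identifiers), an edge filter F and a radius
N, the built network is the induced subgraph of G restricted to
F-surviving edges on the node set

  { v : d(S, v) ≤ N },  d = weighted shortest-path distance,

computed by multi-source 0-1 BFS, then projected to gene-level,
protein-level or mixed representation.  Client-side analyses cover
equivalent nodes (identical open neighborhoods), all-pairs shortest paths
among selected nodes (same 0/1 lengths, deterministic lexicographic
witness), node degree and the Watts–Strogatz local clustering
coefficient C(v) = 2·t(v)/(k(v)(k(v)−1)).

Gene aliases that name several genes, or that equal the official symbol
of a different gene, are ambiguous and discarded during identifier
resolution; every other supported identifier type (Entrez, RefSeq,
UniGene, GenBank, Uniprot) resolves unambiguously.

## Worked example

```python
import tempfile
from bisonet import (NetworkQuery, assemble_supergraph, build_network,
                     build_translation_table, load_datastore,
                     make_worked_examples)

tmp = tempfile.mkdtemp()
make_worked_examples(tmp)                   # packaged demonstration store
store = load_datastore(tmp)
graph = assemble_supergraph(store)
table = build_translation_table(store.identifiers, store.entities)

q = NetworkQuery(organism=9606, identify_kinds={"gene"},
                 distance=1, output_mode="genes_only")
net = build_network(["CPM"], q, store, graph=graph, table=table)
print(net.n_nodes, sorted(net.labels().values()))
```

prints

```
4 ['CPM', 'EGF', 'HBA1', 'HBA2']
```

— the CPM product interacts with the products of HBA1, HBA2 and EGF, so
the distance-1 gene-level network has exactly those four genes (each gene
rides along with its product through a zero-length coding edge).
Selecting the three added genes and expanding once more grows the network
to 11 genes, and equivalent-node detection on it reports one five-member
set — AHSP, FECH, HEMGN, HP, HPX — all interacting with exactly
{HBA1, HBA2}.  The scripts in `examples/` run these workflows end to end
and print what every number means.

The same pipeline is available from the shell:

```bash
bisonet fixtures --preset worked-examples --out store
printf 'CPM\n' > ids.txt
bisonet build --ids ids.txt --store store --organism 9606 \
        --kinds gene --distance 1 --output-mode genes --out cpm.xml
bisonet stats --net cpm.xml
bisonet expand --net cpm.xml --select HBA1,HBA2,EGF --store store \
        --organism 9606 --distance 1 --out expanded.xml
bisonet equiv --net expanded.xml
```

Networks serialize to a versioned XML exchange format (optionally
gzipped; see `docs/network-xml.md`) and export to Cytoscape-consumable
SIF and GraphML; external SIF/edge-list networks can be converted into
annotated `bisonet` networks when their node names use supported
identifiers.  `docs/methods.md` documents the model, the projection
semantics, the disambiguation rules and the synthetic-data generators.

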