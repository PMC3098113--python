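"""Coding relations: splice variants and shared protein products.

Builds a mixed gene/protein network from the multi-isoform gene HLA-A.
Because coding edges have length zero, an N=0 query from the gene already
contains every splice-variant product, and at N=1 the network shows a
protein (UBIQ_HUMAN) coded by two different genes.
"""

import tempfile

from bisonet import (
    NetworkQuery,
    assemble_supergraph,
    build_network,
    build_translation_table,
    load_datastore,
    make_worked_examples,
    shortest_paths,
)

with tempfile.TemporaryDirectory() as tmp:
    make_worked_examples(tmp)
    store = load_datastore(tmp)
    graph = assemble_supergraph(store)
    table = build_translation_table(store.identifiers, store.entities)

    def build(n):
        q = NetworkQuery(organism=9606, identify_kinds={"gene"}, distance=n,
                         output_mode="genes_and_proteins_with_coding")
        # symbols match case-insensitively: "hla-a" finds HLA-A
        return build_network(["hla-a"], q, store, graph=graph, table=table)

    zero, one = build(0), build(1)

    print("N=0:", ", ".join(sorted(zero.labels().values())))
    print("N=1:", ", ".join(sorted(one.labels().values())))

    coding_into_ubiq = [
        d for _, _, d in one.graph.edges(data=True)
        if d["rel_type"] == "coding" and one.node_attrs(d["dst"])["label"] == "UBIQ_HUMAN"
    ]
    print(f"coding edges into UBIQ_HUMAN: {len(coding_into_ubiq)} "
          f"(from {', '.join(sorted(one.node_attrs(d['src'])['label'] for d in coding_into_ubiq))})")

    (res,) = shortest_paths(one, ["G_UBB", "G_UBC"])
    print(f"distance UBB .. UBC: {res.length} (two zero-length coding hops)")

# The N=0 network already holds the gene plus its three splice-variant
# proteins; interaction partners (and their genes) enter at N=1.  Two
# genes coding one protein sit at distance zero from each other.
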