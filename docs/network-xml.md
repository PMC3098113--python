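# Network exchange format (schema version 1.0)

A `BuiltNetwork` serializes to a UTF-8 XML document, optionally gzipped
(the gzip header carries no timestamp, so output is byte-deterministic).
`parse_network` is the exact inverse; gzip is auto-detected from the
magic bytes.

```xml
<?xml version="1.0" encoding="UTF-8"?>
<network schema_version="1.0">
  <query organism="9606" identify_kinds="gene" sources="" methods=""
         rel_types="coding|pdna|ppi" distance="1" output_mode="genes_only"/>
  <nodes>
    <node id="G_CPM" kind="gene" label="CPM" seed="true" distance="0">
      <description>carboxypeptidase M</description>
      <go>GO:0004181|GO:0005886</go>
      <pathways/>
    </node>
    ...
  </nodes>
  <edges>
    <edge id="I001" rel_type="ppi" src="P_CPM" dst="P_HBA1" dashed="false">
      <evidence source_db="HPRD" method="two hybrid" pubmed="11283024"/>
      <evidence source_db="BioGRID" method="affinity chromatography technology"
                pubmed="14702039"/>
    </edge>
    ...
  </edges>
  <unresolved>
    <token value="garbage1" status="unresolved"/>
  </unresolved>
</network>
```

Element reference:

| element | content |
| --- | --- |
| `network@schema_version` | must equal `1.0`; anything else is rejected |
| `query` | echo of the request that produced the network (optional; absent for hand-assembled networks). Set-valued fields are pipe-joined, empty string = unrestricted |
| `conversion_stats` | present only for converted external networks; `resolved`/`unresolved`/`discarded` name counts |
| `node` | `id` internal id; `kind` is `gene`, `protein` or `external` (unresolved imported name); `seed`/`distance` expansion provenance; child elements hold description, pipe-joined GO ids and pathway ids |
| `edge` | `id` edge key; `rel_type` one of `coding`, `ppi`, `pdna`, `imported` (anything else is a fatal parse error); `src`/`dst` record the stored direction (gene→product for coding, protein→gene for pdna); `dashed` is the coding-relation render hint |
| `evidence` | one element per supporting observation; `pubmed` pipe-joins integer ids |
| `unresolved/token` | input tokens that contributed no node, with status |

Nodes are sorted by id and edges by key, so serializing the same network
twice yields identical bytes. Truncated or damaged gzip payloads raise a
"corrupt payload" error; malformed XML reports the parser position.
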