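# biokgraph

Context-specific biomedical knowledge graphs from entity lists.

Researchers analysing an omics experiment usually end up with a list of
genes (or metabolites), and the evidence needed to interpret it — disease
associations, drug mechanisms, pathway memberships, interaction partners,
expression sites — is scattered across independent databases with
incompatible identifiers and query languages. `biokgraph` turns such a
list (or a differential-expression result table) into one typed,
provenance-tracked knowledge graph (KG): it harmonizes identifiers onto
canonical namespaces, runs pluggable per-source annotators through an
injectable transport, merges their assertions under a fixed schema, and
serializes the result for Cytoscape, Neo4j, or a triple store.

## The data model

The graph is a property graph with a closed schema:

* **18 node types** — gene, disease, compound, anatomical entity,
  pathway, molecular function, biological process, cellular component,
  side effect, homolog, phenotype, miRNA, transcription factor,
  mitochondrial pathway, key event, molecular initiating event, adverse
  outcome pathway, adverse outcome.
* **10 directed relations** — interacts_with, part_of, associated_with,
  expressed_by, activates, inhibits, treats, has_side_effect,
  upstream_of, downstream_of.

Node identity is a canonical `NAMESPACE:accession` key (Entrez for genes,
UMLS for diseases, PubChem for compounds); edge identity is the
(subject, relation, object) triple. When several sources assert the same
triple the edge is stored once and its provenance accumulates one
(source, version, retrieval date) entry per source. Protein-level
assertions are folded onto gene nodes.

A catalog registers 15 data sources with their query dialects (REST API,
GraphQL, SPARQL, or file download); five of them — DisGeNET, OpenTargets,
MINERVA, STRING, Bgee — ship with concrete query builders and response
parsers, each frozen against recorded fixture responses and replayable
with `biokgraph selftest`. Offline runs use a deterministic fixture
transport that synthesizes valid responses per source, keyed by
`(seed, source, entity)`, so any run is exactly reproducible.

Exports: Cytoscape-style JSON (`.cyjs`), typed GraphML (round-trips
losslessly back into the library), and RDF Turtle modeled with SIO / RO /
BFO classes and predicates, with SHACL shapes generated from the classes a
graph actually uses. A `TriplestoreManager` wraps a GraphDB-style REST
API behind an injectable transport.

## Worked example

```bash
biokgraph demo-inputs --genes 10 --output-dir demo
biokgraph run --input demo/dea.tsv --kind dea_table \
    --mapping demo/mappings.tsv --seed 7 --output-dir demo/out
```

The first command writes a synthetic 10-gene differential-expression
table (`identifier`, `log2fc`, `p_value`) and a BridgeDb-style mapping
table with Entrez/Ensembl/HGNC/STRING cross-references. The second
harmonizes the genes, queries the default four-source selection
(DisGeNET, OpenTargets, MINERVA, STRING) through the fixture transport,
builds the graph, and writes `graph.cyjs`, `graph.graphml`, `graph.ttl`,
`graph.shacl.ttl`, plus `summary.json` and `report.json`. With seed 7 the
summary reads:

```json
{
  "node_count_total": 23,
  "edge_count_total": 101,
  "nodes_by_type": {"compound": 3, "disease": 5, "gene": 10, "pathway": 5},
  "edges_by_relation": {"activates": 5, "associated_with": 35, "inhibits": 8,
                        "interacts_with": 14, "part_of": 31, "treats": 8},
  "edges_by_source": {"DisGeNET": 19, "MINERVA": 20, "OpenTargets": 57, "STRING": 14}
}
```

All 10 input genes mapped and were annotated; the four-source selection
contributes exactly five node-pair edge categories (gene–disease,
gene–compound, disease–compound, gene–pathway, gene–gene). Per-source
counts sum to more than the edge total because an edge asserted by two
sources counts once per source. `report.json` embeds the full
query-metadata list (source, version, retrieval date, batch and result
sizes, duration), so every artifact is traceable to the queries that
built it.

From Python the same pipeline is:

```python
from biokgraph import RunConfig, run
report = run(RunConfig(input_path="demo/dea.tsv", input_kind="dea_table",
                       mapping_path="demo/mappings.tsv",
                       output_dir="demo/out", seed=7))
print(report.summary.node_count_total)
```

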