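# Methods

This note documents the models, conventions, and numerical choices behind
`biokgraph`, and what its synthetic test conditions do and do not show.

## Harmonization

Input kinds are a gene/protein list, a metabolite/compound list, or a
differential-expression (DEA) table. DEA rows are genes that additionally
carry an effect size (log2 fold-change) and a significance value in
[0, 1]; these statistics are preserved on the resulting gene nodes rather
than used for filtering — the package does no raw-data processing and
expects a pre-filtered table.

Identifier mapping consumes BridgeDb-style rows
(source namespace, source id, target namespace, target id). Canonical
target namespaces default to Entrez (genes), UMLS (diseases), PubChem
(compounds), overridable per entity kind. Conventions, chosen where the
underlying design was open:

* **Canonical key format** `NAMESPACE:accession`, namespace uppercased,
  accession verbatim — unambiguous, sortable, CURIE-like.
* **One-to-many mappings**: the lexicographically smallest target
  accession becomes the canonical key; all other reachable accessions
  (including the source-side identifiers of every matched mapping row)
  are retained as cross-references. Deterministic without needing
  preference data; recorded in the table's mapping provenance.
* **Chain depth**: direct source→target plus at most one pivot hop
  through an explicitly configured hub namespace. Full transitive
  closure is off because multi-hop chains across mapping tables are a
  known source of spurious identifier links.
* **Duplicates**: inputs mapping to one canonical key merge; identical
  DEA statistics merge silently, conflicting ones raise an error.
  Averaging conflicting evidence would silently corrupt it.
* Inputs without a namespace prefix match mapping rows by accession in
  any source namespace; prefixed inputs (`ENTREZ:7157`) match only their
  declared namespace and map to themselves when already canonical.

## Annotation

The catalog holds one descriptor per source: query dialect, supported
entity kinds, and the typed edge categories it can contribute. Edge
categories per source are fixed so that the DisGeNET + OpenTargets +
MINERVA + STRING selection contributes exactly the five node-pair
categories gene–disease, gene–compound, disease–compound, gene–pathway,
gene–gene; GO-component membership (gene—part_of→BP/MF/CC) is carried by
the g:Profiler catalog entry. MitoCarta and TFLink publish tabular
downloads rather than a query endpoint and are registered with a FILE
dialect.

Annotators run per source, independently: a transport failure in one
source is converted into an explicit failure record and the other
sources' results are untouched. Batches default to 25 identifiers per
request (bounded query size, batching in input order). Every (source,
batch) query is stamped with metadata — source version, ISO retrieval
date, input and result counts, wall-clock duration. Durations are
recorded for the run report but excluded from serialized graphs so that
exports are byte-reproducible; they are never asserted in tests.

Rows carry an `anchor_key` — the harmonized entity the query was issued
for, which must be present in the table — while subject and object keep
the assertion's natural direction. This is required because some
categories place the anchored gene on the object side (a drug *inhibits*
a gene) or on neither side (that drug *treats* a disease).

Relation directions are fixed as: gene—associated_with→disease,
compound—activates/inhibits→gene, compound—treats→disease,
gene—part_of→pathway/GO component, gene—interacts_with—gene, and
gene—expressed_by→anatomical entity with edge attributes for expression
level, developmental stage, and an over/under-expression flag.
Self-loops are permitted only for interacts_with (self-interaction);
other relations reject them at validation.

## Synthetic transport and what it shows

The fixture transport synthesizes one response per (source, batch) in the
source's native shape: a REST JSON envelope for DisGeNET/MINERVA/STRING
shapes, a GraphQL `data` envelope for OpenTargets, SPARQL JSON results
for Bgee. Each (entity, candidate object) pair is included iff a
SHA-256-derived uniform float keyed on (seed, source, entity, object) is
below the density parameter (default 0.4); scores and stages derive from
the same stream. Candidate pools are small, clearly synthetic sets of
diseases, drugs, pathways, and anatomical entities whose accession
patterns follow each namespace's conventions.

The synthetic 10-gene DEA study (symbols `GS1..GS10`, log2 fold-changes
in [-3, 3], p-values in (0, 0.05]) emulates a significance-filtered
differential-expression table at a deliberately small scale; 10 genes and
default density keep the end-to-end run near 100 edges, which exercises
merging, multi-source provenance, and every serializer within seconds.

What passing tests show: structural correctness — identifier partition,
merge determinism and commutativity, vocabulary closure, round-trip and
conformance guarantees, per-source isolation. What they do not show:
anything about real endpoint behaviour (rate limits, pagination, live
schema drift, authentication) or about the biological plausibility of
real database content; the response shapes are faithful in structure,
minimal in field coverage.

## Graph construction

Node merging is keyed by canonical key; a key asserted with two node
types is an error naming the offending assertions. Attribute collisions
on merge are resolved last-writer-wins (in canonical row order, so the
result is order-independent) with a logged warning — except DEA
statistics, which raise. Edge merging accumulates deduplicated,
sorted provenance entries. Rows are processed in sorted
(subject, relation, object, metadata ref) order, making the built graph
invariant to the order sources were queried in.

## Serialization

* **Cytoscape JSON**: plain `.cyjs`-style elements document (nodes and
  edges arrays), chosen over the CX stream as the simplest stable
  dialect; elements and keys sorted for stable bytes. Provenance is a
  `;`-delimited list of `source|version|date` strings.
* **GraphML**: typed attribute keys declared once; structured payloads
  (xrefs, attribute records, provenance, build metadata) stored as
  canonical JSON strings, which is what makes the importer reconstruct
  the graph exactly, types included.
* **RDF**: classes and predicates come from a versioned mapping file
  (`rdf_mapping.json`) covering all 18 types and 10 relations with SIO,
  RO, BFO, GO, and AOP-ontology IRIs; the exact IRIs are configuration,
  not code. Numeric attributes use the SIO measurement-value pattern
  (4 triples each). `associated_with` edges are reified as first-class
  association nodes (`sio:Association` with two `sio:has_part`
  participants); other relations are direct triples with an
  `rdf:Statement` anchor. Each provenance entry adds 5 triples to the
  edge's anchor. Reification nodes use deterministic IRIs (indexed over
  sorted edges) rather than blank nodes, and the Turtle output is sorted
  N-Triples lines — portable across triple stores and byte-stable.
  The total triple count is therefore an exact affine function of the
  element counts, which tests verify against an independent per-element
  enumerator.
* **SHACL**: one node shape per instantiated class, one property shape
  per observed predicate, with `sh:nodeKind`, `sh:datatype` (when
  uniform) and `sh:minCount 1` (when universal). Shape generation is
  paired with a subset validator covering exactly these constraint
  kinds; mutation tests confirm the validator detects removed required
  values and wrong value kinds. ShEx output is not generated.

## Analysis

Subgraph extraction expands an undirected neighborhood (context
neighborhoods are about proximity, not direction) and then applies type
and relation filters, always keeping anchors; direction and provenance
are preserved in the result. Training-set export emits one positive row
per edge and `floor(ratio × |edges|)` negatives sampled uniformly with a
seeded generator from type-compatible non-edges, where compatibility is
the union of the catalog's edge categories; requesting more negatives
than exist is an explicit infeasibility error. The uniform
type-compatible scheme is this package's own choice of negative sampler.
Summary plots are simple matplotlib bar charts; only file existence and
non-emptiness are contractual.

## Pipeline

The `run` orchestration executes harmonize → annotate → build →
analyze/export, injecting any configured context nodes (e.g. a disease
of interest linked to all mapped input entities with a provenance tag)
before validation. Configuration is TOML with CLI flags winning on
conflict. Live mode is deliberately unconfigured out of the box: offline
runs use the fixture transport, and the test suite never contacts a
network. Problem sizes used throughout the tests (2–10 genes, up to ~50
nodes per generated graph, 25–100 graphs per property suite) were chosen
to exercise all code paths with comfortable margins on a single CPU.

## Known limitations

* Ten of the 15 catalog sources are contract-only stubs; selecting them
  for annotation raises an unsupported-source error.
* No ontology-aware reasoning (no subsumption, no transitive part_of).
* No fuzzy or probabilistic identifier matching; unmapped inputs are
  reported, not guessed.
* The retained per-source attribute sets are minimal (scores, expression
  context, mechanism of action), not the sources' full schemas.
* Publication/patent enrichment is surfaced as a summary field but no
  literature adapter ships.
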