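"""Registry of the 15 supported data sources and the annotation runner.

Each descriptor records a source's query dialect, the biological entity
kinds it accepts, and the typed edge categories it can contribute to the
graph. Five sources (DisGeNET, OpenTargets, MINERVA, STRING, Bgee) ship
with concrete query builders and response parsers; the remaining ten are
catalog-registered stubs that document the contract without an
implementation.

Every annotation run is stamped with :class:`QueryMetadata` — source
version, retrieval date, batch size, result-set size, and wall-clock
duration — so a graph remains traceable to the exact queries that built it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Callable, Iterable, Mapping, Sequence

from .errors import CatalogLookupError, TransportError, UnsupportedSourceError
from .harmonize import HarmonizedTable
from .vocab import NODE_TYPES, RELATIONS

EdgeCategory = tuple[str, str, str]  # (subject node type, relation, object node type)


@dataclass(frozen=True)
class DataSourceDescriptor:
    """One catalog entry: a data source and what it can contribute."""

    name: str
    query_dialect: str  # SPARQL | API | GraphQL | FILE
    supported_entities: frozenset[str]
    edge_categories: frozenset[EdgeCategory]
    concrete: bool = False

    def __post_init__(self) -> None:
        if not self.edge_categories:
            raise ValueError(f"{self.name}: edge_categories must be non-empty")
        for subj, rel, obj in self.edge_categories:
            if subj not in NODE_TYPES or obj not in NODE_TYPES or rel not in RELATIONS:
                raise ValueError(
                    f"{self.name}: edge category ({subj}, {rel}, {obj}) outside vocabularies"
                )


@dataclass(frozen=True)
class QueryMetadata:
    """Provenance record for one (source, batch) query."""

    metadata_id: str
    source_name: str
    source_version: str
    retrieval_date: str  # ISO-8601
    input_count: int
    result_count: int
    duration_seconds: float

    def __post_init__(self) -> None:
        date.fromisoformat(self.retrieval_date)
        if self.input_count < 0 or self.result_count < 0 or self.duration_seconds < 0:
            raise ValueError("counts and duration must be non-negative")


@dataclass(frozen=True)
class AnnotationRow:
    """One typed assertion emitted by an adapter.

    ``anchor_key`` is the harmonized input entity the query was issued for;
    it must belong to the annotated table. The (subject, relation, object)
    triple carries the assertion in its natural direction, which may place
    the anchor on either side (e.g. a drug *inhibits* an input gene) or on
    neither (a drug *treats* a disease discovered while annotating a gene).
    """

    anchor_key: str
    subject_key: str
    subject_type: str
    relation: str
    object_key: str
    object_type: str
    subject_attributes: Mapping[str, Any] = field(default_factory=dict)
    object_attributes: Mapping[str, Any] = field(default_factory=dict)
    edge_attributes: Mapping[str, Any] = field(default_factory=dict)
    source_field_map: Mapping[str, str] = field(default_factory=dict)
    metadata_ref: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"relation {self.relation!r} outside the 10-relation vocabulary")
        for t in (self.subject_type, self.object_type):
            if t not in NODE_TYPES:
                raise ValueError(f"node type {t!r} outside the 18-type vocabulary")


@dataclass(frozen=True)
class SourceFailure:
    """Explicit record of one failed source (or skipped key) in a run."""

    source_name: str
    error_class: str
    message: str


def _cats(*triples: EdgeCategory) -> frozenset[EdgeCategory]:
    return frozenset(triples)


_CATALOG: tuple[DataSourceDescriptor, ...] = (
    DataSourceDescriptor(
        "AOP WIKI RDF",
        "SPARQL",
        frozenset({"gene", "compound", "key_event", "molecular_initiating_event",
                   "adverse_outcome_pathway", "adverse_outcome"}),
        _cats(
            ("molecular_initiating_event", "upstream_of", "key_event"),
            ("key_event", "upstream_of", "adverse_outcome"),
            ("key_event", "part_of", "adverse_outcome_pathway"),
            ("adverse_outcome", "downstream_of", "key_event"),
            ("gene", "part_of", "adverse_outcome_pathway"),
        ),
    ),
    DataSourceDescriptor(
        "Bgee",
        "SPARQL",
        frozenset({"gene", "anatomical_entity"}),
        _cats(("gene", "expressed_by", "anatomical_entity")),
        concrete=True,
    ),
    DataSourceDescriptor(
        "DisGeNET",
        "API",
        frozenset({"gene", "disease"}),
        _cats(("gene", "associated_with", "disease")),
        concrete=True,
    ),
    DataSourceDescriptor(
        "g:Profiler",
        "API",
        frozenset({"gene", "pathway", "biological_process", "molecular_function",
                   "cellular_component"}),
        _cats(
            ("gene", "part_of", "biological_process"),
            ("gene", "part_of", "molecular_function"),
            ("gene", "part_of", "cellular_component"),
        ),
    ),
    DataSourceDescriptor(
        "IntAct",
        "API",
        frozenset({"gene", "compound"}),
        _cats(("gene", "interacts_with", "gene"), ("compound", "interacts_with", "gene")),
    ),
    DataSourceDescriptor(
        "KEGG",
        "API",
        frozenset({"compound", "gene", "pathway"}),
        _cats(("gene", "part_of", "pathway"), ("compound", "part_of", "pathway")),
    ),
    DataSourceDescriptor(
        "MINERVA",
        "API",
        frozenset({"compound", "gene", "pathway"}),
        _cats(("gene", "part_of", "pathway")),
        concrete=True,
    ),
    DataSourceDescriptor(
        "MitoCarta",
        "FILE",
        frozenset({"gene", "mitochondrial_pathway"}),
        _cats(("gene", "part_of", "mitochondrial_pathway")),
    ),
    DataSourceDescriptor(
        "MolMeDB",
        "SPARQL",
        frozenset({"compound", "gene"}),
        _cats(("compound", "inhibits", "gene")),
    ),
    DataSourceDescriptor(
        "OpenTargets",
        "GraphQL",
        frozenset({"compound", "gene", "pathway", "biological_process",
                   "molecular_function", "cellular_component", "disease"}),
        _cats(
            ("gene", "associated_with", "disease"),
            ("compound", "activates", "gene"),
            ("compound", "inhibits", "gene"),
            ("compound", "treats", "disease"),
            ("gene", "part_of", "pathway"),
        ),
        concrete=True,
    ),
    DataSourceDescriptor(
        "PubChem",
        "SPARQL",
        frozenset({"compound", "gene"}),
        _cats(("compound", "activates", "gene"), ("compound", "inhibits", "gene")),
    ),
    DataSourceDescriptor(
        "STRING",
        "API",
        frozenset({"gene"}),
        _cats(("gene", "interacts_with", "gene")),
        concrete=True,
    ),
    DataSourceDescriptor(
        "TFLink",
        "FILE",
        frozenset({"transcription_factor", "gene"}),
        _cats(
            ("transcription_factor", "activates", "gene"),
            ("transcription_factor", "inhibits", "gene"),
        ),
    ),
    DataSourceDescriptor(
        "Wikidata",
        "SPARQL",
        frozenset({"gene"}),
        _cats(("gene", "associated_with", "disease")),
    ),
    DataSourceDescriptor(
        "WikiPathways",
        "SPARQL",
        frozenset({"gene", "pathway"}),
        _cats(("gene", "part_of", "pathway")),
    ),
)


def default_catalog() -> list[DataSourceDescriptor]:
    """The 15 shipped source descriptors, in stable (alphabetical) order."""
    return list(_CATALOG)


def get_descriptor(name: str, catalog: Sequence[DataSourceDescriptor] | None = None) -> DataSourceDescriptor:
    for d in catalog if catalog is not None else _CATALOG:
        if d.name == name:
            return d
    raise CatalogLookupError(f"unknown data source {name!r}")


def edge_categories_for(
    catalog: Sequence[DataSourceDescriptor],
    selected: Iterable[str],
) -> set[EdgeCategory]:
    """Union of edge categories contributed by the selected sources."""
    out: set[EdgeCategory] = set()
    for name in selected:
        out |= get_descriptor(name, catalog).edge_categories
    return out


def collapse_to_node_pairs(categories: Iterable[EdgeCategory]) -> set[tuple[str, str]]:
    """Collapse (subject, relation, object) categories to unordered node-type pairs."""
    return {tuple(sorted((s, o))) for s, _r, o in categories}


def export_catalog_json(catalog: Sequence[DataSourceDescriptor] | None = None) -> str:
    """Stable JSON rendering of the catalog (for CLIs / UIs)."""
    docs = [
        {
            "name": d.name,
            "query_dialect": d.query_dialect,
            "supported_entities": sorted(d.supported_entities),
            "edge_categories": sorted(list(c) for c in d.edge_categories),
            "concrete": d.concrete,
        }
        for d in (catalog if catalog is not None else _CATALOG)
    ]
    return json.dumps(docs, indent=2, sort_keys=False)


def annotate(
    table: HarmonizedTable,
    selected: Iterable[str],
    fetcher: Callable[..., Any],
    batch_size: int = 25,
) -> tuple[list[AnnotationRow], list[QueryMetadata], list[SourceFailure]]:
    """Run the selected annotators over a harmonized table.

    Sources are queried independently: a transport failure in one source
    becomes an explicit :class:`SourceFailure` record and does not abort
    the others. Returns (rows, metadata, failures); every row's
    ``metadata_ref`` points at the :class:`QueryMetadata` of the batch that
    produced it, and each metadata's ``result_count`` equals the number of
    rows referencing it.
    """
    from . import adapters

    if batch_size < 1:
        raise ValueError("batch_size must be positive")

    rows: list[AnnotationRow] = []
    metadata: list[QueryMetadata] = []
    failures: list[SourceFailure] = []
    version = getattr(fetcher, "source_version", "unknown")
    today = date.today().isoformat()

    for source in sorted(set(selected)):
        descriptor = get_descriptor(source)
        if not descriptor.concrete:
            raise UnsupportedSourceError(
                f"source {source!r} is a catalog stub without a concrete adapter"
            )
        adapter = adapters.get_adapter(source)
        keys, skips = adapter.translate_batch(table)
        failures.extend(skips)
        for b, start in enumerate(range(0, len(keys), batch_size)):
            batch = keys[start : start + batch_size]
            meta_id = f"{source}#{b}"
            t0 = time.perf_counter()
            try:
                request = adapter.build_request(batch)
                response = fetcher(request)
                if response.status >= 400:
                    raise TransportError(
                        f"{source}: transport returned status {response.status}"
                    )
                batch_rows = adapter.parse_response(response, batch, metadata_ref=meta_id)
            except Exception as exc:  # per-source isolation, surfaced explicitly
                failures.append(
                    SourceFailure(source, type(exc).__name__, str(exc))
                )
                break
            duration = time.perf_counter() - t0
            metadata.append(
                QueryMetadata(
                    metadata_id=meta_id,
                    source_name=source,
                    source_version=version,
                    retrieval_date=today,
                    input_count=len(batch),
                    result_count=len(batch_rows),
                    duration_seconds=duration,
                )
            )
            rows.extend(batch_rows)
    return rows, metadata, failures


def failure_report_jsonl(failures: Sequence[SourceFailure]) -> str:
    """JSON-lines rendering of per-source failures."""
    return "\n".join(
        json.dumps(
            {"source": f.source_name, "error_class": f.error_class, "message": f.message}
        )
        for f in failures
    )
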