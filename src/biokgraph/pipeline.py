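"""End-to-end orchestration: harmonize → annotate → build → analyze/export.

A :class:`RunConfig` describes one run — input file and kind, mapping
source, selected annotators, fetcher mode, context nodes to inject,
export formats, output directory. :func:`run` executes the four stages in
order, writes the requested exports, and returns a report embedding the
full query-metadata list so every artifact is reproducible from the
report alone. Per-source failures never abort a run; they are surfaced in
the report's failure section. Query durations are reported but kept out
of the serialized graphs, so identical config and seed yield
byte-identical export files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import analyze, catalog, fixtures, harmonize, serialize
from .errors import ConfigurationError
from .graph import PropertyGraph, add_context_node, build_graph, validate_graph


@dataclass
class ContextNodeSpec:
    """A context node to inject, linked to all mapped input entities."""

    key: str
    node_type: str
    label: str
    relation: str = "associated_with"
    provenance_tag: str = "user-context"
    link_to: Sequence[str] | None = None  # None → all input entities


@dataclass
class RunConfig:
    input_path: str
    input_kind: str
    mapping_path: str
    output_dir: str
    selected_sources: Sequence[str] = ("DisGeNET", "OpenTargets", "MINERVA", "STRING")
    column_map: Mapping[str, str] | None = None
    fetcher_mode: str = "fixture"  # fixture | live
    seed: int = 0
    density: float = 0.4
    batch_size: int = 25
    export_formats: Sequence[str] = ("cytoscape", "graphml", "rdf")
    generate_shapes: bool = True
    base_iri: str = "https://biokgraph.example.org"
    context_nodes: Sequence[ContextNodeSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.input_kind not in harmonize.INPUT_KINDS:
            raise ConfigurationError(f"unknown input kind {self.input_kind!r}")
        if self.fetcher_mode not in ("fixture", "live"):
            raise ConfigurationError(f"unknown fetcher mode {self.fetcher_mode!r}")
        known = {d.name for d in catalog.default_catalog()}
        unknown = set(self.selected_sources) - known
        if unknown:
            raise ConfigurationError(f"unknown sources selected: {sorted(unknown)}")
        bad = set(self.export_formats) - set(serialize.EXPORT_FORMATS)
        if bad:
            raise ConfigurationError(f"unknown export formats: {sorted(bad)}")


@dataclass
class RunReport:
    artifacts: dict[str, str]
    summary: analyze.GraphSummary
    query_metadata: list[catalog.QueryMetadata]
    failures: list[catalog.SourceFailure]
    edge_node_pair_categories: list[list[str]]
    mapped_count: int
    unmapped_count: int
    validation_violations: list[str]

    def to_json(self) -> str:
        doc = {
            "artifacts": self.artifacts,
            "summary": self.summary.__dict__,
            "query_metadata": [asdict(m) for m in self.query_metadata],
            "failures": [asdict(f) for f in self.failures],
            "edge_node_pair_categories": self.edge_node_pair_categories,
            "mapped_count": self.mapped_count,
            "unmapped_count": self.unmapped_count,
            "validation_violations": self.validation_violations,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _edge_node_pairs(graph: PropertyGraph) -> list[list[str]]:
    pairs = {
        tuple(sorted((graph.nodes[e.subject_key].node_type,
                      graph.nodes[e.object_key].node_type)))
        for e in graph.edges.values()
    }
    return [list(p) for p in sorted(pairs)]


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``config``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. harmonize
    raw = Path(config.input_path).read_text(encoding="utf-8")
    records = harmonize.parse_input(raw, config.input_kind, config.column_map)
    mappings, provenance = harmonize.load_mapping_table(config.mapping_path)
    table = harmonize.map_identifiers(records, mappings, mapping_provenance=provenance)
    harmonize.write_unmapped_report(table, out / "unmapped.tsv")

    # 2. annotate
    if config.fetcher_mode == "live":
        raise ConfigurationError(
            "live fetcher mode requires explicitly configured endpoints; "
            "offline runs use fetcher_mode='fixture'"
        )
    fetcher = fixtures.fixture_fetcher(config.seed, config.density)
    rows, metadata, failures = catalog.annotate(
        table, config.selected_sources, fetcher, config.batch_size
    )

    # 3. build
    graph = build_graph(table, rows, metadata)
    for spec in config.context_nodes:
        targets = spec.link_to if spec.link_to is not None else table.keys()
        add_context_node(
            graph,
            spec.key,
            spec.node_type,
            spec.label,
            [(t, spec.relation, spec.provenance_tag) for t in targets],
        )
    violations = validate_graph(graph)

    # 4. analyze + export
    summary = analyze.summarize(graph)
    artifacts: dict[str, str] = {}
    if "cytoscape" in config.export_formats:
        path = out / "graph.cyjs"
        path.write_text(serialize.to_cytoscape_json(graph), encoding="utf-8")
        artifacts["cytoscape"] = str(path)
    if "graphml" in config.export_formats:
        path = out / "graph.graphml"
        path.write_text(serialize.to_graphml(graph), encoding="utf-8")
        artifacts["graphml"] = str(path)
    if "rdf" in config.export_formats:
        policy = serialize.UriPolicy(base_iri=config.base_iri)
        rdf_graph = serialize.to_rdf(graph, policy=policy)
        path = out / "graph.ttl"
        path.write_text(serialize.serialize_turtle(rdf_graph), encoding="utf-8")
        artifacts["rdf"] = str(path)
        if config.generate_shapes:
            shapes = serialize.generate_shacl(graph, policy=policy, rdf_graph=rdf_graph)
            spath = out / "graph.shacl.ttl"
            spath.write_text(serialize.serialize_turtle(shapes), encoding="utf-8")
            artifacts["shacl"] = str(spath)

    (out / "summary.json").write_text(summary.to_json(), encoding="utf-8")
    (out / "failures.jsonl").write_text(
        catalog.failure_report_jsonl(failures), encoding="utf-8"
    )

    report = RunReport(
        artifacts=artifacts,
        summary=summary,
        query_metadata=metadata,
        failures=failures,
        edge_node_pair_categories=_edge_node_pairs(graph),
        mapped_count=len(table.rows),
        unmapped_count=len(table.unmapped),
        validation_violations=violations,
    )
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report
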