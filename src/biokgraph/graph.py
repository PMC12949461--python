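"""Typed, provenance-tracked property graph and its construction.

The graph merges harmonized input entities with annotation rows into one
deduplicated structure: node identity is the canonical key, edge identity
is the (subject, relation, object) triple. When several sources assert
the same triple, the edge is kept once and its provenance list
accumulates one (source, version, retrieval date) entry per source —
every edge therefore remains traceable to the queries that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Iterable, Sequence

import networkx as nx

from .catalog import AnnotationRow, QueryMetadata
from .errors import IntegrityError, MergeConflictError, NodeTypeConflictError
from .harmonize import HarmonizedTable
from .vocab import ENTITY_KIND_TO_NODE_TYPE, NODE_TYPES, RELATIONS

logger = logging.getLogger(__name__)

#: One provenance entry: (source name, source version, retrieval date).
ProvenanceEntry = tuple[str, str, str]

EdgeKey = tuple[str, str, str]

_SCALARS = (str, int, float, bool, type(None))

#: Node attributes that must never be silently overwritten on merge.
_PROTECTED_ATTRS = ("effect_size", "significance")


def _is_serializable(value: Any) -> bool:
    if isinstance(value, _SCALARS):
        return True
    if isinstance(value, (list, tuple)):
        return all(isinstance(v, _SCALARS) for v in value)
    return False


@dataclass
class GraphNode:
    key: str
    node_type: str
    label: str
    xrefs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass
class GraphEdge:
    subject_key: str
    relation: str
    object_key: str
    provenance: list[ProvenanceEntry] = field(default_factory=list)
    attributes: dict[str, Any] = field(default_factory=dict)

    @property
    def key(self) -> EdgeKey:
        return (self.subject_key, self.relation, self.object_key)


@dataclass
class PropertyGraph:
    nodes: dict[str, GraphNode] = field(default_factory=dict)
    edges: dict[EdgeKey, GraphEdge] = field(default_factory=dict)
    build_metadata: list[dict[str, Any]] = field(default_factory=list)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[GraphNode]:
        return [self.nodes[k] for k in sorted(self.nodes)]

    def sorted_edges(self) -> list[GraphEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node in self.sorted_nodes():
            g.add_node(node.key, node_type=node.node_type, label=node.label)
        for edge in self.sorted_edges():
            g.add_edge(edge.subject_key, edge.object_key, key=edge.relation)
        return g

    def structural_signature(self) -> tuple:
        """Order-independent content signature used by equality checks."""
        return (
            tuple(
                (n.key, n.node_type, n.label,
                 tuple(sorted((ns, accs) for ns, accs in n.xrefs.items())),
                 tuple(sorted((k, _freeze(v)) for k, v in n.attributes.items())))
                for n in self.sorted_nodes()
            ),
            tuple(
                (e.key, tuple(sorted(e.provenance)),
                 tuple(sorted((k, _freeze(v)) for k, v in e.attributes.items())))
                for e in self.sorted_edges()
            ),
        )


def _freeze(value: Any):
    return tuple(value) if isinstance(value, list) else value


def _merge_attributes(node: GraphNode, incoming: dict[str, Any]) -> None:
    """Last-writer-wins per attribute, except protected DEA statistics."""
    for k, v in incoming.items():
        if k in node.attributes and node.attributes[k] != v:
            if k in _PROTECTED_ATTRS:
                raise MergeConflictError(
                    f"node {node.key}: conflicting values for protected attribute {k!r}: "
                    f"{node.attributes[k]!r} vs {v!r}"
                )
            logger.warning(
                "node %s: attribute %r overwritten (%r -> %r)",
                node.key, k, node.attributes[k], v,
            )
        node.attributes[k] = v


def _ensure_node(
    graph: PropertyGraph,
    key: str,
    node_type: str,
    label: str,
    attributes: dict[str, Any] | None = None,
    asserted_by: str = "",
) -> GraphNode:
    existing = graph.nodes.get(key)
    if existing is None:
        node = GraphNode(key=key, node_type=node_type, label=label or key)
        graph.nodes[key] = node
    else:
        node = existing
        if node.node_type != node_type:
            raise NodeTypeConflictError(
                f"key {key} asserted as both {node.node_type!r} and {node_type!r}"
                + (f" (by {asserted_by})" if asserted_by else "")
            )
        if label and (not node.label or node.label == node.key):
            node.label = label
    if attributes:
        _merge_attributes(node, dict(attributes))
    return node


def _provenance_for(row: AnnotationRow, meta: dict[str, QueryMetadata]) -> ProvenanceEntry:
    m = meta.get(row.metadata_ref)
    if m is not None:
        return (m.source_name, m.source_version, m.retrieval_date)
    return ("user-supplied", "n/a", date.today().isoformat())


def build_graph(
    table: HarmonizedTable,
    rows: Sequence[AnnotationRow],
    metadata: Sequence[QueryMetadata] = (),
) -> PropertyGraph:
    """Merge a harmonized table and annotation rows into one property graph.

    Every table entity becomes a node even if unannotated (flagged
    ``from_input``); DEA statistics are copied onto gene nodes. Rows are
    processed in a canonical sort order so that the result is independent
    of the order sources were queried in.
    """
    graph = PropertyGraph()
    meta_by_id = {m.metadata_id: m for m in metadata}
    table_keys = set(table.keys())

    for hrow in table.rows:
        attrs: dict[str, Any] = {"from_input": True}
        if hrow.original.dea_stats is not None:
            attrs["effect_size"] = hrow.original.dea_stats.effect_size
            attrs["significance"] = hrow.original.dea_stats.significance
        node = _ensure_node(
            graph,
            hrow.canonical_key,
            ENTITY_KIND_TO_NODE_TYPE[hrow.original.entity_kind],
            label=hrow.original.raw_identifier,
            attributes=attrs,
        )
        node.xrefs = {ns: tuple(accs) for ns, accs in sorted(hrow.cross_references.items())}

    for row in sorted(
        rows, key=lambda r: (r.subject_key, r.relation, r.object_key, r.metadata_ref)
    ):
        if row.anchor_key not in table_keys:
            raise IntegrityError(
                f"annotation row anchored at {row.anchor_key!r}, "
                "which is not in the harmonized table"
            )
        subj_attrs = dict(row.subject_attributes)
        subj_label = subj_attrs.pop("name", "")
        _ensure_node(graph, row.subject_key, row.subject_type, subj_label,
                     subj_attrs, asserted_by=row.metadata_ref)
        obj_attrs = dict(row.object_attributes)
        obj_label = obj_attrs.pop("name", "")
        _ensure_node(graph, row.object_key, row.object_type, obj_label,
                     obj_attrs, asserted_by=row.metadata_ref)

        edge = graph.edges.get((row.subject_key, row.relation, row.object_key))
        if edge is None:
            edge = GraphEdge(row.subject_key, row.relation, row.object_key)
            graph.edges[edge.key] = edge
        entry = _provenance_for(row, meta_by_id)
        if entry not in edge.provenance:
            edge.provenance.append(entry)
            edge.provenance.sort()
        for k, v in row.edge_attributes.items():
            if k in edge.attributes and edge.attributes[k] != v:
                logger.warning("edge %s: attribute %r overwritten", edge.key, k)
            edge.attributes[k] = v

    graph.build_metadata = [
        {
            "metadata_id": m.metadata_id,
            "source_name": m.source_name,
            "source_version": m.source_version,
            "retrieval_date": m.retrieval_date,
            "input_count": m.input_count,
            "result_count": m.result_count,
        }
        for m in metadata
    ]
    graph.build_metadata.append(
        {"harmonization_provenance": table.mapping_provenance}
    )
    return graph


def add_context_node(
    graph: PropertyGraph,
    key: str,
    node_type: str,
    label: str,
    links: Iterable[tuple[str, str, str]] = (),
    retrieval_date: str | None = None,
) -> PropertyGraph:
    """Inject a context node (e.g. a disease of interest) with typed links.

    Each link is (entity key, relation, provenance tag); the edge runs
    from the linked entity to the context node, and its provenance entry
    records the supplied tag as the source. Re-adding an existing key
    merges instead of duplicating.
    """
    if node_type not in NODE_TYPES:
        raise NodeTypeConflictError(f"node type {node_type!r} outside the vocabulary")
    links = list(links)
    for entity_key, relation, _tag in links:
        if entity_key not in graph.nodes:
            raise IntegrityError(f"context link references missing node {entity_key!r}")
        if relation not in RELATIONS:
            raise IntegrityError(f"context link relation {relation!r} outside the vocabulary")
    node = _ensure_node(graph, key, node_type, label, {"context_node": True})
    if label:
        node.label = label
    when = retrieval_date or date.today().isoformat()
    for entity_key, relation, tag in links:
        edge = graph.edges.get((entity_key, relation, key))
        if edge is None:
            edge = GraphEdge(entity_key, relation, key)
            graph.edges[edge.key] = edge
        entry = (tag, "n/a", when)
        if entry not in edge.provenance:
            edge.provenance.append(entry)
            edge.provenance.sort()
    return graph


def validate_graph(graph: PropertyGraph) -> list[str]:
    """Return a list of invariant violations; empty iff the graph is valid."""
    violations: list[str] = []
    for node in graph.sorted_nodes():
        if node.node_type not in NODE_TYPES:
            violations.append(f"node {node.key}: type {node.node_type!r} outside vocabulary")
        for attr, value in node.attributes.items():
            if not _is_serializable(value):
                violations.append(
                    f"node {node.key}: attribute {attr!r} is not a scalar or list of scalars"
                )
    for edge in graph.sorted_edges():
        for endpoint in (edge.subject_key, edge.object_key):
            if endpoint not in graph.nodes:
                violations.append(
                    f"edge {edge.key}: dangling endpoint {endpoint!r}"
                )
        if edge.relation not in RELATIONS:
            violations.append(f"edge {edge.key}: relation outside vocabulary")
        if not edge.provenance:
            violations.append(f"edge {edge.key}: empty provenance")
        if edge.subject_key == edge.object_key and edge.relation != "interacts_with":
            violations.append(
                f"edge {edge.key}: self-loop only allowed for interacts_with"
            )
        for attr, value in edge.attributes.items():
            if not _is_serializable(value):
                violations.append(
                    f"edge {edge.key}: attribute {attr!r} is not a scalar or list of scalars"
                )
    return violations
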