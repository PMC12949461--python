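"""Cytoscape-style JSON export (.cyjs elements document)."""

from __future__ import annotations

import json
from typing import Any

from ..errors import SerializationError
from ..graph import PropertyGraph, _is_serializable


def _check(owner: str, attr: str, value: Any) -> Any:
    if not _is_serializable(value):
        raise SerializationError(
            f"{owner}: attribute {attr!r} is not representable as a JSON scalar/list"
        )
    return list(value) if isinstance(value, tuple) else value


def to_cytoscape_json(graph: PropertyGraph) -> str:
    """Serialize to a Cytoscape elements document (nodes/edges arrays).

    Elements are sorted by node key / edge triple and the JSON keys are
    sorted, so output bytes are stable for a given graph.
    """
    nodes = []
    for node in graph.sorted_nodes():
        data: dict[str, Any] = {
            "id": node.key,
            "node_type": node.node_type,
            "label": node.label,
        }
        for ns, accs in sorted(node.xrefs.items()):
            data[f"xref_{ns.lower()}"] = list(accs)
        for attr, value in sorted(node.attributes.items()):
            data[attr] = _check(f"node {node.key}", attr, value)
        nodes.append({"data": data})

    edges = []
    for edge in graph.sorted_edges():
        data = {
            "id": f"{edge.subject_key}|{edge.relation}|{edge.object_key}",
            "source": edge.subject_key,
            "target": edge.object_key,
            "relation": edge.relation,
            "provenance": ";".join("|".join(p) for p in sorted(edge.provenance)),
        }
        for attr, value in sorted(edge.attributes.items()):
            data[attr] = _check(f"edge {edge.key}", attr, value)
        edges.append({"data": data})

    document = {
        "format_version": "1.0",
        "generated_by": "biokgraph",
        "elements": {"nodes": nodes, "edges": edges},
    }
    return json.dumps(document, indent=2, sort_keys=True)
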