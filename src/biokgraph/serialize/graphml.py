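"""GraphML export/import with exact round-trip semantics.

Attribute keys are declared once in the header (Neo4j/APOC-compatible
typed GraphML). Node and edge payloads that are structured (xrefs,
attribute records, provenance) are stored as JSON strings under declared
keys, which preserves value types exactly across a round trip —
``from_graphml(to_graphml(g))`` reconstructs ``g`` including attribute
types and per-edge provenance.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

from ..errors import GraphFormatError
from ..graph import GraphEdge, GraphNode, PropertyGraph

_NS = "http://graphml.graphdrawing.org/xmlns"

#: (key id, domain, attribute name)
_KEYS = (
    ("nt", "node", "node_type"),
    ("nl", "node", "label"),
    ("nx", "node", "xrefs"),
    ("na", "node", "attributes"),
    ("er", "edge", "relation"),
    ("ep", "edge", "provenance"),
    ("ea", "edge", "attributes"),
    ("gm", "graph", "build_metadata"),
)


def to_graphml(graph: PropertyGraph) -> str:
    root = ET.Element("graphml", xmlns=_NS)
    for key_id, domain, name in _KEYS:
        ET.SubElement(
            root, "key",
            {"id": key_id, "for": domain, "attr.name": name, "attr.type": "string"},
        )
    g = ET.SubElement(root, "graph", {"id": "G", "edgedefault": "directed"})

    def data(parent: ET.Element, key_id: str, text: str) -> None:
        el = ET.SubElement(parent, "data", {"key": key_id})
        el.text = text

    data(g, "gm", json.dumps(graph.build_metadata, sort_keys=True))
    for node in graph.sorted_nodes():
        el = ET.SubElement(g, "node", {"id": node.key})
        data(el, "nt", node.node_type)
        data(el, "nl", node.label)
        data(el, "nx", json.dumps({ns: list(a) for ns, a in node.xrefs.items()},
                                  sort_keys=True))
        data(el, "na", json.dumps(node.attributes, sort_keys=True))
    for i, edge in enumerate(graph.sorted_edges()):
        el = ET.SubElement(
            g, "edge",
            {"id": f"e{i}", "source": edge.subject_key, "target": edge.object_key},
        )
        data(el, "er", edge.relation)
        data(el, "ep", json.dumps([list(p) for p in edge.provenance], sort_keys=True))
        data(el, "ea", json.dumps(edge.attributes, sort_keys=True))

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _collect_data(el: ET.Element, declared: set[str], owner: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for d in el.findall(f"{{{_NS}}}data"):
        key = d.get("key", "")
        if key not in declared:
            raise GraphFormatError(
                f"{owner}: data element references undeclared key {key!r}"
            )
        out[key] = d.text or ""
    return out


def from_graphml(document: str) -> PropertyGraph:
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise GraphFormatError(f"not well-formed XML: {exc}") from exc
    declared = {k.get("id", "") for k in root.findall(f"{{{_NS}}}key")}
    g = root.find(f"{{{_NS}}}graph")
    if g is None:
        raise GraphFormatError("document has no <graph> element")

    graph = PropertyGraph()
    graph_data = _collect_data(g, declared, "graph")
    if "gm" in graph_data and graph_data["gm"]:
        graph.build_metadata = json.loads(graph_data["gm"])

    for el in g.findall(f"{{{_NS}}}node"):
        node_id = el.get("id")
        if node_id is None:
            raise GraphFormatError("node element without id")
        data = _collect_data(el, declared, f"node {node_id}")
        for required in ("nt", "nl", "nx", "na"):
            if required not in data:
                raise GraphFormatError(f"node {node_id}: missing declared key {required!r}")
        graph.nodes[node_id] = GraphNode(
            key=node_id,
            node_type=data["nt"],
            label=data["nl"],
            xrefs={ns: tuple(a) for ns, a in json.loads(data["nx"]).items()},
            attributes=json.loads(data["na"]),
        )
    for el in g.findall(f"{{{_NS}}}edge"):
        edge_id = el.get("id", "?")
        source, target = el.get("source"), el.get("target")
        if source is None or target is None:
            raise GraphFormatError(f"edge {edge_id}: missing source/target")
        data = _collect_data(el, declared, f"edge {edge_id}")
        for required in ("er", "ep", "ea"):
            if required not in data:
                raise GraphFormatError(f"edge {edge_id}: missing declared key {required!r}")
        edge = GraphEdge(
            subject_key=source,
            relation=data["er"],
            object_key=target,
            provenance=[tuple(p) for p in json.loads(data["ep"])],
            attributes=json.loads(data["ea"]),
        )
        graph.edges[edge.key] = edge
    return graph
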