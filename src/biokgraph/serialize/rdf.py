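"""RDF serialization of the property graph.

Node types map onto ontology classes and relations onto predicates from
SIO, RO, BFO and the AOP ontology via a versioned mapping file
(``rdf_mapping.json``); the exact IRIs are configuration, not code.

Modeling conventions:

* every node: one ``rdf:type`` triple + one ``rdfs:label`` triple, plus
  one ``skos:exactMatch`` triple per cross-reference;
* numeric attributes use the SIO measurement-value pattern (4 triples:
  link, type, label, value);
* non-numeric scalar attributes are one datatype-property triple each
  (lists: one triple per element);
* ``associated_with`` edges are reified as first-class association nodes
  (``sio:Association`` with two ``sio:has_part`` participants); all other
  relations are direct triples plus an ``rdf:Statement`` anchor so that
  provenance can attach to them;
* each provenance entry adds 5 triples (entity, type, label/source,
  version, date) hanging off the edge's anchor.

Serialization emits sorted N-Triples lines (a valid Turtle subset), so
output bytes are a pure function of graph content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import DCTERMS, SKOS, XSD

from ..errors import ConfigurationError, SerializationError
from ..graph import PropertyGraph
from ..vocab import NODE_TYPES, RELATIONS, split_key

PROV = Namespace("http://www.w3.org/ns/prov#")
VOID = Namespace("http://rdfs.org/ns/void#")


@dataclass(frozen=True)
class RdfMappingTable:
    """Node-class / relation-predicate correspondence for the RDF export."""

    node_classes: dict[str, str]
    relation_predicates: dict[str, str]
    measurement: dict[str, str]
    association: dict[str, str]
    version: str = "1"

    def __post_init__(self) -> None:
        missing_types = NODE_TYPES - set(self.node_classes)
        missing_rels = RELATIONS - set(self.relation_predicates)
        if missing_types or missing_rels:
            raise ConfigurationError(
                f"RDF mapping not total: missing node types {sorted(missing_types)}, "
                f"relations {sorted(missing_rels)}"
            )
        for iri in (*self.node_classes.values(), *self.relation_predicates.values()):
            if "://" not in iri:
                raise ConfigurationError(f"{iri!r} is not an absolute IRI")


def default_rdf_mapping() -> RdfMappingTable:
    """Load the shipped versioned mapping file."""
    doc = json.loads(
        (resources.files(__package__) / "rdf_mapping.json").read_text(encoding="utf-8")
    )
    return RdfMappingTable(
        node_classes=doc["node_classes"],
        relation_predicates=doc["relation_predicates"],
        measurement=doc["measurement"],
        association=doc["association"],
        version=doc.get("version", "1"),
    )


def _default_entity_iri(base: str, namespace: str, accession: str) -> str:
    return f"{base}/id/{namespace}/{accession}"


@dataclass(frozen=True)
class UriPolicy:
    """How canonical keys become IRIs (identifiers-registry style)."""

    base_iri: str = "https://biokgraph.example.org"
    entity_iri: Callable[[str, str, str], str] = _default_entity_iri

    def node_iri(self, key: str) -> URIRef:
        ns, acc = split_key(key)
        return URIRef(self.entity_iri(self.base_iri, ns, acc))

    def vocab_iri(self, name: str) -> URIRef:
        return URIRef(f"{self.base_iri}/vocab/{name}")


def _is_numeric(value) -> bool:
    return isinstance(value, (int, float)) and not isinstance(value, bool)


def _attr_triples(g: Graph, owner: URIRef, attr: str, value,
                  mapping: RdfMappingTable, policy: UriPolicy, owner_name: str) -> None:
    if _is_numeric(value):
        mv = URIRef(f"{owner}/mv/{attr}")
        g.add((owner, URIRef(mapping.measurement["has_measurement_value"]), mv))
        g.add((mv, RDF.type, URIRef(mapping.measurement["measurement_value_class"])))
        g.add((mv, RDFS.label, Literal(attr)))
        g.add((mv, URIRef(mapping.measurement["has_value"]), Literal(value, datatype=XSD.double)))
    elif isinstance(value, (list, tuple)):
        for item in value:
            g.add((owner, policy.vocab_iri(attr), Literal(item)))
    elif isinstance(value, (str, bool)) or value is None:
        if value is not None:
            g.add((owner, policy.vocab_iri(attr), Literal(value)))
    else:
        raise SerializationError(
            f"{owner_name}: attribute {attr!r} of type {type(value).__name__} "
            "cannot be expressed in RDF"
        )


def to_rdf(
    graph: PropertyGraph,
    mapping: RdfMappingTable | None = None,
    policy: UriPolicy | None = None,
) -> Graph:
    """Build the RDF rendering of a property graph."""
    mapping = mapping or default_rdf_mapping()
    policy = policy or UriPolicy()
    g = Graph()

    dataset = URIRef(f"{policy.base_iri}/dataset")
    g.add((dataset, RDF.type, VOID.Dataset))
    g.add((dataset, RDFS.label, Literal("biokgraph knowledge graph")))
    g.add((dataset, DCTERMS.creator, Literal("biokgraph")))

    for node in graph.sorted_nodes():
        iri = policy.node_iri(node.key)
        g.add((iri, RDF.type, URIRef(mapping.node_classes[node.node_type])))
        g.add((iri, RDFS.label, Literal(node.label)))
        for ns, accs in sorted(node.xrefs.items()):
            for acc in accs:
                xref = URIRef(_default_entity_iri(policy.base_iri, ns, acc))
                g.add((iri, SKOS.exactMatch, xref))
        for attr, value in sorted(node.attributes.items()):
            _attr_triples(g, iri, attr, value, mapping, policy, f"node {node.key}")

    for i, edge in enumerate(graph.sorted_edges()):
        subj = policy.node_iri(edge.subject_key)
        obj = policy.node_iri(edge.object_key)
        if edge.relation == "associated_with":
            anchor = URIRef(f"{policy.base_iri}/assoc/{i}")
            g.add((anchor, RDF.type, URIRef(mapping.association["association_class"])))
            g.add((anchor, URIRef(mapping.association["has_part"]), subj))
            g.add((anchor, URIRef(mapping.association["has_part"]), obj))
        else:
            predicate = URIRef(mapping.relation_predicates[edge.relation])
            g.add((subj, predicate, obj))
            anchor = URIRef(f"{policy.base_iri}/statement/{i}")
            g.add((anchor, RDF.type, RDF.Statement))
            g.add((anchor, RDF.subject, subj))
            g.add((anchor, RDF.predicate, predicate))
            g.add((anchor, RDF.object, obj))
        for j, (source, version, when) in enumerate(sorted(edge.provenance)):
            p = URIRef(f"{anchor}/prov/{j}")
            g.add((anchor, PROV.wasDerivedFrom, p))
            g.add((p, RDF.type, PROV.Entity))
            g.add((p, RDFS.label, Literal(source)))
            g.add((p, DCTERMS.hasVersion, Literal(version)))
            g.add((p, DCTERMS.date, Literal(when)))
        for attr, value in sorted(edge.attributes.items()):
            _attr_triples(g, anchor, attr, value, mapping, policy, f"edge {edge.key}")
    return g


def serialize_turtle(g: Graph) -> str:
    """Deterministic Turtle bytes: sorted N-Triples lines."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g
    )
    return "\n".join(lines) + "\n"
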