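"""SHACL shape generation for the RDF export, plus a conformance checker.

Shapes are derived from the classes actually instantiated in a given
graph — one node shape per used node type, with one property constraint
per predicate observed on instances of that class. Constraints emitted:
``sh:targetClass``, ``sh:path``, ``sh:nodeKind``, ``sh:datatype`` (when
all observed objects share one literal datatype) and ``sh:minCount 1``
(when every instance carries the predicate).

:func:`validate_shacl` is a self-contained validator for exactly this
constraint subset; it checks an RDF data graph against a shapes graph and
reports violations per focus node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, RDF, URIRef

from ..graph import PropertyGraph
from .rdf import RdfMappingTable, UriPolicy, default_rdf_mapping, to_rdf

SH = Namespace("http://www.w3.org/ns/shacl#")


def _shape_name(node_type: str) -> str:
    return "".join(part.capitalize() for part in node_type.split("_")) + "Shape"


def generate_shacl(
    graph: PropertyGraph,
    mapping: RdfMappingTable | None = None,
    policy: UriPolicy | None = None,
    rdf_graph: Graph | None = None,
) -> Graph:
    """Generate node shapes for the classes used by ``graph``'s RDF form."""
    mapping = mapping or default_rdf_mapping()
    policy = policy or UriPolicy()
    data = rdf_graph if rdf_graph is not None else to_rdf(graph, mapping, policy)
    shapes = Graph()
    shapes.bind("sh", SH)

    used_types = sorted({n.node_type for n in graph.nodes.values()})
    for node_type in used_types:
        cls = URIRef(mapping.node_classes[node_type])
        instances = sorted(data.subjects(RDF.type, cls))
        if not instances:
            continue
        shape = URIRef(f"{policy.base_iri}/shapes/{_shape_name(node_type)}")
        shapes.add((shape, RDF.type, SH.NodeShape))
        shapes.add((shape, SH.targetClass, cls))

        predicates = sorted(
            {p for inst in instances for p in data.predicates(inst, None) if p != RDF.type}
        )
        for k, pred in enumerate(predicates):
            objects = [o for inst in instances for o in data.objects(inst, pred)]
            # IRI-identified property shapes keep serialization byte-stable
            pshape = URIRef(f"{shape}/prop/{k}")
            shapes.add((shape, SH.property, pshape))
            shapes.add((pshape, SH.path, pred))
            if all(isinstance(o, URIRef) for o in objects):
                shapes.add((pshape, SH.nodeKind, SH.IRI))
            elif all(isinstance(o, Literal) for o in objects):
                shapes.add((pshape, SH.nodeKind, SH.Literal))
                datatypes = {o.datatype for o in objects}
                if len(datatypes) == 1 and None not in datatypes:
                    shapes.add((pshape, SH.datatype, datatypes.pop()))
            if all(any(True for _ in data.objects(inst, pred)) for inst in instances):
                shapes.add((pshape, SH.minCount, Literal(1)))
    return shapes


@dataclass
class ShaclReport:
    conforms: bool
    violations: list[str] = field(default_factory=list)


def validate_shacl(data: Graph, shapes: Graph) -> ShaclReport:
    """Check ``data`` against ``shapes`` (subset validator, see module doc)."""
    violations: list[str] = []
    for shape in shapes.subjects(RDF.type, SH.NodeShape):
        target = shapes.value(shape, SH.targetClass)
        if target is None:
            continue
        focus_nodes = sorted(data.subjects(RDF.type, target))
        for pshape in shapes.objects(shape, SH.property):
            path = shapes.value(pshape, SH.path)
            node_kind = shapes.value(pshape, SH.nodeKind)
            datatype = shapes.value(pshape, SH.datatype)
            cls = shapes.value(pshape, SH["class"])
            min_count = shapes.value(pshape, SH.minCount)
            max_count = shapes.value(pshape, SH.maxCount)
            for focus in focus_nodes:
                values = list(data.objects(focus, path))
                if min_count is not None and len(values) < int(min_count):
                    violations.append(
                        f"{focus}: fewer than {min_count} values for {path}"
                    )
                if max_count is not None and len(values) > int(max_count):
                    violations.append(
                        f"{focus}: more than {max_count} values for {path}"
                    )
                for v in values:
                    if node_kind == SH.IRI and not isinstance(v, URIRef):
                        violations.append(f"{focus}: value {v!r} of {path} is not an IRI")
                    if node_kind == SH.Literal and not isinstance(v, Literal):
                        violations.append(f"{focus}: value {v!r} of {path} is not a literal")
                    if datatype is not None and (
                        not isinstance(v, Literal) or v.datatype != datatype
                    ):
                        violations.append(
                            f"{focus}: value of {path} lacks datatype {datatype}"
                        )
                    if cls is not None and (v, RDF.type, cls) not in data:
                        violations.append(
                            f"{focus}: value {v} of {path} is not an instance of {cls}"
                        )
    return ShaclReport(conforms=not violations, violations=violations)
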