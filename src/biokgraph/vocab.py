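"""Closed node-type and relation vocabularies of the knowledge-graph schema.

The property-graph data model is deliberately closed: every node carries one
of 18 type labels and every directed edge one of 10 relation labels. Sources
contribute assertions only within these vocabularies, which keeps merged
graphs queryable with a stable schema regardless of which annotators ran.
"""

from __future__ import annotations

#: The 18 node types of the property-graph data model.
NODE_TYPES: frozenset[str] = frozenset(
    {
        "gene",
        "disease",
        "compound",
        "anatomical_entity",
        "pathway",
        "molecular_function",
        "biological_process",
        "cellular_component",
        "side_effect",
        "homolog",
        "phenotype",
        "mirna",
        "transcription_factor",
        "mitochondrial_pathway",
        "key_event",
        "molecular_initiating_event",
        "adverse_outcome_pathway",
        "adverse_outcome",
    }
)

#: The 10 directed relation types.
RELATIONS: frozenset[str] = frozenset(
    {
        "interacts_with",
        "part_of",
        "associated_with",
        "expressed_by",
        "activates",
        "inhibits",
        "treats",
        "has_side_effect",
        "upstream_of",
        "downstream_of",
    }
)

#: Entity kinds accepted on input. Proteins are folded onto genes; metabolite
#: and compound are synonyms here (canonicalized to compound nodes).
ENTITY_KINDS: frozenset[str] = frozenset({"gene", "metabolite"})

#: Default canonical namespace per input entity kind: Entrez gene identifiers
#: for genes, PubChem compound identifiers for metabolites/compounds.
#: Diseases are canonicalized to UMLS by the annotators.
DEFAULT_NAMESPACE_POLICY: dict[str, str] = {
    "gene": "ENTREZ",
    "metabolite": "PUBCHEM",
}

#: Node type a harmonized input entity becomes in the graph.
ENTITY_KIND_TO_NODE_TYPE: dict[str, str] = {
    "gene": "gene",
    "metabolite": "compound",
}


def make_key(namespace: str, accession: str) -> str:
    """Build a canonical ``NAMESPACE:accession`` key (namespace uppercased)."""
    return f"{namespace.upper()}:{accession}"


def split_key(key: str) -> tuple[str, str]:
    """Split a canonical key into (namespace, accession)."""
    namespace, _, accession = key.partition(":")
    return namespace, accession
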