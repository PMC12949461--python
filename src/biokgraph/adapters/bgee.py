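"""Gene expression-site adapter (Bgee-shaped SPARQL endpoint).

One SPARQL query lists the batch's Ensembl ids in a VALUES clause; results
arrive in the standard SPARQL JSON results format. Each binding yields a
gene —expressed_by→ anatomical-entity assertion annotated with the
expression level, the developmental stage, and whether the gene is over-
or under-expressed at that site.
"""

from __future__ import annotations

import json
from typing import Sequence

from ..catalog import AnnotationRow
from ..errors import SchemaDriftError
from ..vocab import make_key
from .base import Adapter, BatchKey, RandFn, RawResponse, reverse_map
from .pools import ANATOMICAL_ENTITIES, STAGES

_QUERY_TEMPLATE = """PREFIX genex: <http://purl.org/genex#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?gene ?anat ?anatName ?expressionLevel ?stage ?direction
WHERE {{
  VALUES ?gene {{ {values} }}
  ?expression genex:hasSequenceUnit ?gene .
  ?expression genex:hasAnatomicalEntity ?anat .
  ?anat rdfs:label ?anatName .
  ?expression genex:hasExpressionLevel ?expressionLevel .
  ?expression genex:hasDevelopmentalStage ?stage .
  ?expression genex:hasDirection ?direction .
}}"""

_VARS = ("gene", "anat", "anatName", "expressionLevel", "stage", "direction")


class BgeeAdapter(Adapter):
    name = "Bgee"
    dialect = "SPARQL"
    subject_namespace = "ENSEMBL"

    def build_request(self, batch: Sequence[BatchKey]):
        values = " ".join(f'"{acc}"' for _, acc in batch)
        return self._request(batch, _QUERY_TEMPLATE.format(values=values))

    def parse_response(self, response: RawResponse, batch: Sequence[BatchKey],
                       metadata_ref: str = "") -> list[AnnotationRow]:
        to_canonical = reverse_map(batch)
        try:
            doc = json.loads(response.body)
        except json.JSONDecodeError as exc:
            raise SchemaDriftError(f"Bgee: body is not valid JSON ({exc})") from exc
        try:
            bindings = doc["results"]["bindings"]
        except (TypeError, KeyError) as exc:
            raise SchemaDriftError("Bgee: missing results.bindings") from exc
        rows: list[AnnotationRow] = []
        for i, binding in enumerate(bindings):
            for var in _VARS:
                if var not in binding or "value" not in binding[var]:
                    raise SchemaDriftError(f"Bgee: results.bindings[{i}].{var} missing")
            subject = to_canonical.get(binding["gene"]["value"])
            if subject is None:
                continue
            uberon = binding["anat"]["value"].rsplit("UBERON_", 1)[-1]
            rows.append(
                AnnotationRow(
                    anchor_key=subject,
                    subject_key=subject,
                    subject_type="gene",
                    relation="expressed_by",
                    object_key=make_key("UBERON", uberon),
                    object_type="anatomical_entity",
                    object_attributes={"name": binding["anatName"]["value"]},
                    edge_attributes={
                        "expression_level": float(binding["expressionLevel"]["value"]),
                        "developmental_stage": binding["stage"]["value"],
                        "over_expressed": binding["direction"]["value"] == "over",
                    },
                    source_field_map={
                        "expression_level": "expressionLevel",
                        "developmental_stage": "stage",
                        "over_expressed": "direction",
                    },
                    metadata_ref=metadata_ref,
                )
            )
        return rows

    def fixture_response(self, request, rand: RandFn, density: float) -> str:
        bindings = []
        for acc in request.source_accessions:
            for uberon, label in ANATOMICAL_ENTITIES:
                if rand(acc, uberon) >= density:
                    continue
                stage = STAGES[int(rand(acc, uberon, "stage") * len(STAGES)) % len(STAGES)]
                bindings.append(
                    {
                        "gene": {"type": "literal", "value": acc},
                        "anat": {
                            "type": "uri",
                            "value": f"http://purl.obolibrary.org/obo/UBERON_{uberon}",
                        },
                        "anatName": {"type": "literal", "value": label},
                        "expressionLevel": {
                            "type": "literal",
                            "value": str(round(100 * rand(acc, uberon, "level"), 2)),
                        },
                        "stage": {"type": "literal", "value": stage},
                        "direction": {
                            "type": "literal",
                            "value": "over" if rand(acc, uberon, "dir") < 0.5 else "under",
                        },
                    }
                )
        return json.dumps(
            {"head": {"vars": list(_VARS)}, "results": {"bindings": bindings}},
            sort_keys=True,
        )
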