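"""Target annotation adapter (OpenTargets-shaped GraphQL API).

One GraphQL document queries every gene in the batch (aliased fields,
Ensembl ids inlined once each) for disease associations, known drugs, and
pathway memberships. Emitted assertions:

* gene —associated_with→ disease (disease re-keyed to UMLS via dbXRefs)
* compound —activates|inhibits→ gene (mechanism of action)
* compound —treats→ disease
* gene —part_of→ pathway (Reactome)
"""

from __future__ import annotations

import json
from typing import Sequence

from ..catalog import AnnotationRow
from ..errors import SchemaDriftError
from ..vocab import make_key
from .base import Adapter, BatchKey, RandFn, RawResponse
from .pools import DRUGS, EFO_DISEASES, REACTOME_PATHWAYS

_TARGET_FIELDS = (
    "{ id approvedSymbol "
    "associatedDiseases { rows { disease { id name dbXRefs } score } } "
    "knownDrugs { rows { drug { id name pubchemCid } mechanismOfAction "
    "disease { id dbXRefs } } } "
    "pathways { id name } }"
)

_MECHANISMS_ACTIVATE = {"agonist", "activator", "partial agonist"}
_MECHANISMS_INHIBIT = {"inhibitor", "antagonist", "inverse agonist", "blocker"}


def _umls_from_xrefs(xrefs: list[str], fallback_id: str) -> str:
    for x in xrefs:
        if x.upper().startswith("UMLS:"):
            return make_key("UMLS", x.split(":", 1)[1])
    return make_key("EFO", fallback_id)


class OpenTargetsAdapter(Adapter):
    name = "OpenTargets"
    dialect = "GraphQL"
    subject_namespace = "ENSEMBL"

    def build_request(self, batch: Sequence[BatchKey]):
        fields = " ".join(
            f't{i}: target(ensemblId: "{acc}") {_TARGET_FIELDS}'
            for i, (_, acc) in enumerate(batch)
        )
        return self._request(batch, f"query annotateTargets {{ {fields} }}")

    def parse_response(self, response: RawResponse, batch: Sequence[BatchKey],
                       metadata_ref: str = "") -> list[AnnotationRow]:
        try:
            doc = json.loads(response.body)
        except json.JSONDecodeError as exc:
            raise SchemaDriftError(f"OpenTargets: body is not valid JSON ({exc})") from exc
        data = doc.get("data") if isinstance(doc, dict) else None
        if not isinstance(data, dict):
            raise SchemaDriftError("OpenTargets: missing top-level 'data' object")
        rows: list[AnnotationRow] = []
        for i, (canonical, _acc) in enumerate(batch):
            target = data.get(f"t{i}")
            if target is None:
                continue
            path = f"data.t{i}"
            for section in ("associatedDiseases", "knownDrugs", "pathways"):
                if section not in target:
                    raise SchemaDriftError(f"OpenTargets: {path} lacks field {section!r}")

            for j, arow in enumerate(target["associatedDiseases"].get("rows", [])):
                disease = arow.get("disease")
                if disease is None or "id" not in disease:
                    raise SchemaDriftError(
                        f"OpenTargets: {path}.associatedDiseases.rows[{j}].disease.id missing"
                    )
                rows.append(
                    AnnotationRow(
                        anchor_key=canonical,
                        subject_key=canonical,
                        subject_type="gene",
                        relation="associated_with",
                        object_key=_umls_from_xrefs(disease.get("dbXRefs", []), disease["id"]),
                        object_type="disease",
                        object_attributes={"name": disease.get("name", "")},
                        edge_attributes={"score": float(arow["score"])},
                        source_field_map={"score": "score", "name": "disease.name"},
                        metadata_ref=metadata_ref,
                    )
                )

            for j, drow in enumerate(target["knownDrugs"].get("rows", [])):
                drug = drow.get("drug")
                if drug is None or "id" not in drug:
                    raise SchemaDriftError(
                        f"OpenTargets: {path}.knownDrugs.rows[{j}].drug.id missing"
                    )
                cid = drug.get("pubchemCid")
                compound_key = (
                    make_key("PUBCHEM", cid) if cid else make_key("CHEMBL", drug["id"])
                )
                mechanism = (drow.get("mechanismOfAction") or "").lower()
                if mechanism in _MECHANISMS_ACTIVATE:
                    relation = "activates"
                elif mechanism in _MECHANISMS_INHIBIT:
                    relation = "inhibits"
                else:
                    # unknown mechanism: keep the assertion, store the raw value
                    relation = "inhibits"
                compound_attrs = {
                    "name": drug.get("name", ""),
                    "raw_mechanism_of_action": drow.get("mechanismOfAction", ""),
                }
                rows.append(
                    AnnotationRow(
                        anchor_key=canonical,
                        subject_key=compound_key,
                        subject_type="compound",
                        relation=relation,
                        object_key=canonical,
                        object_type="gene",
                        subject_attributes=compound_attrs,
                        source_field_map={"name": "drug.name"},
                        metadata_ref=metadata_ref,
                    )
                )
                ddis = drow.get("disease")
                if ddis and "id" in ddis:
                    rows.append(
                        AnnotationRow(
                            anchor_key=canonical,
                            subject_key=compound_key,
                            subject_type="compound",
                            relation="treats",
                            object_key=_umls_from_xrefs(ddis.get("dbXRefs", []), ddis["id"]),
                            object_type="disease",
                            subject_attributes={"name": drug.get("name", "")},
                            metadata_ref=metadata_ref,
                        )
                    )

            for j, pw in enumerate(target["pathways"]):
                if "id" not in pw:
                    raise SchemaDriftError(
                        f"OpenTargets: {path}.pathways[{j}].id missing"
                    )
                rows.append(
                    AnnotationRow(
                        anchor_key=canonical,
                        subject_key=canonical,
                        subject_type="gene",
                        relation="part_of",
                        object_key=make_key("REACTOME", pw["id"]),
                        object_type="pathway",
                        object_attributes={"name": pw.get("name", "")},
                        source_field_map={"name": "name"},
                        metadata_ref=metadata_ref,
                    )
                )
        return rows

    def fixture_response(self, request, rand: RandFn, density: float) -> str:
        data = {}
        for i, acc in enumerate(request.source_accessions):
            diseases = [
                {
                    "disease": {"id": efo, "name": label, "dbXRefs": [f"UMLS:{cui}"]},
                    "score": round(0.1 + 0.9 * rand(acc, efo, "score"), 3),
                }
                for efo, cui, label in EFO_DISEASES
                if rand(acc, efo) < density
            ]
            drugs = []
            for chembl, cid, name, mechanism in DRUGS:
                if rand(acc, chembl) < density:
                    # each drug row also names the disease it is indicated for
                    efo, cui, _label = EFO_DISEASES[
                        int(rand(acc, chembl, "indication") * len(EFO_DISEASES))
                        % len(EFO_DISEASES)
                    ]
                    drugs.append(
                        {
                            "drug": {"id": chembl, "name": name, "pubchemCid": cid},
                            "mechanismOfAction": mechanism,
                            "disease": {"id": efo, "dbXRefs": [f"UMLS:{cui}"]},
                        }
                    )
            pathways = [
                {"id": rid, "name": label}
                for rid, label in REACTOME_PATHWAYS
                if rand(acc, rid) < density
            ]
            data[f"t{i}"] = {
                "id": acc,
                "approvedSymbol": f"SYM{i}",
                "associatedDiseases": {"rows": diseases},
                "knownDrugs": {"rows": drugs},
                "pathways": pathways,
            }
        return json.dumps({"data": data}, sort_keys=True)
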