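"""Gene–disease association adapter (DisGeNET-shaped REST API).

Subjects are queried by Entrez gene id; each association carries the
source's association score. Object diseases are already UMLS-keyed, the
canonical disease namespace, so no object translation is needed.
"""

from __future__ import annotations

import json
from typing import Sequence

from ..catalog import AnnotationRow
from ..errors import SchemaDriftError
from ..vocab import make_key
from .base import Adapter, BatchKey, RandFn, RawResponse, reverse_map
from .pools import DISEASES


class DisgenetAdapter(Adapter):
    name = "DisGeNET"
    dialect = "API"
    subject_namespace = "ENTREZ"

    def build_request(self, batch: Sequence[BatchKey]):
        ids = ",".join(acc for _, acc in batch)
        return self._request(batch, f"gda/summary?gene_ncbi_id={ids}&format=json")

    def parse_response(self, response: RawResponse, batch: Sequence[BatchKey],
                       metadata_ref: str = "") -> list[AnnotationRow]:
        to_canonical = reverse_map(batch)
        try:
            doc = json.loads(response.body)
        except json.JSONDecodeError as exc:
            raise SchemaDriftError(f"DisGeNET: body is not valid JSON ({exc})") from exc
        if not isinstance(doc, dict) or "payload" not in doc:
            raise SchemaDriftError("DisGeNET: missing top-level 'payload' array")
        rows: list[AnnotationRow] = []
        for i, assoc in enumerate(doc["payload"]):
            for f in ("gene_ncbi_id", "disease_umls", "score"):
                if f not in assoc:
                    raise SchemaDriftError(f"DisGeNET: payload[{i}] lacks field {f!r}")
            subject = to_canonical.get(str(assoc["gene_ncbi_id"]))
            if subject is None:
                continue  # subject containment: never emit outside the batch
            rows.append(
                AnnotationRow(
                    anchor_key=subject,
                    subject_key=subject,
                    subject_type="gene",
                    relation="associated_with",
                    object_key=make_key("UMLS", assoc["disease_umls"]),
                    object_type="disease",
                    object_attributes={"name": assoc.get("disease_name", "")},
                    edge_attributes={"score": float(assoc["score"])},
                    source_field_map={"score": "score", "name": "disease_name"},
                    metadata_ref=metadata_ref,
                )
            )
        return rows

    def fixture_response(self, request, rand: RandFn, density: float) -> str:
        payload = []
        for acc in request.source_accessions:
            for cui, label in DISEASES:
                if rand(acc, cui) < density:
                    payload.append(
                        {
                            "gene_ncbi_id": int(acc),
                            "disease_umls": cui,
                            "disease_name": label,
                            "score": round(0.1 + 0.9 * rand(acc, cui, "score"), 3),
                        }
                    )
        return json.dumps({"status": "OK", "payload": payload}, sort_keys=True)
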