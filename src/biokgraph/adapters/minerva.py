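"""Disease-map pathway membership adapter (MINERVA-shaped REST API).

Subjects are queried by HGNC symbol against disease-map models; each model
a symbol occurs in yields one gene—part_of—pathway assertion with the
model id as the pathway accession.
"""

from __future__ import annotations

import json
from typing import Sequence

from ..catalog import AnnotationRow
from ..errors import SchemaDriftError
from ..vocab import make_key
from .base import Adapter, BatchKey, RandFn, RawResponse, reverse_map
from .pools import MINERVA_MODELS


class MinervaAdapter(Adapter):
    name = "MINERVA"
    dialect = "API"
    subject_namespace = "HGNC"

    def build_request(self, batch: Sequence[BatchKey]):
        ids = ",".join(acc for _, acc in batch)
        return self._request(batch, f"projects/synthetic/models:search?symbols={ids}")

    def parse_response(self, response: RawResponse, batch: Sequence[BatchKey],
                       metadata_ref: str = "") -> list[AnnotationRow]:
        to_canonical = reverse_map(batch)
        try:
            doc = json.loads(response.body)
        except json.JSONDecodeError as exc:
            raise SchemaDriftError(f"MINERVA: body is not valid JSON ({exc})") from exc
        if not isinstance(doc, dict) or "models" not in doc:
            raise SchemaDriftError("MINERVA: missing top-level 'models' array")
        rows: list[AnnotationRow] = []
        for i, model in enumerate(doc["models"]):
            for f in ("idObject", "name", "elements"):
                if f not in model:
                    raise SchemaDriftError(f"MINERVA: models[{i}] lacks field {f!r}")
            pathway_key = make_key("MINERVA", str(model["idObject"]))
            for symbol in model["elements"]:
                subject = to_canonical.get(symbol)
                if subject is None:
                    continue
                rows.append(
                    AnnotationRow(
                        anchor_key=subject,
                        subject_key=subject,
                        subject_type="gene",
                        relation="part_of",
                        object_key=pathway_key,
                        object_type="pathway",
                        object_attributes={"name": model["name"]},
                        source_field_map={"name": "name"},
                        metadata_ref=metadata_ref,
                    )
                )
        return rows

    def fixture_response(self, request, rand: RandFn, density: float) -> str:
        models = []
        for model_id, name in MINERVA_MODELS:
            elements = [
                acc
                for acc in request.source_accessions
                if rand(acc, str(model_id)) < density
            ]
            models.append({"idObject": model_id, "name": name, "elements": elements})
        return json.dumps({"models": models}, sort_keys=True)
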