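"""Protein–protein functional interaction adapter (STRING-shaped REST API).

Protein-level interactions are folded onto gene nodes: subjects and
objects are translated from STRING protein identifiers back to canonical
gene keys. Only interactions among the queried batch are returned, so
subject containment holds for both endpoints.
"""

from __future__ import annotations

import json
from typing import Sequence

from ..catalog import AnnotationRow
from ..errors import SchemaDriftError
from .base import Adapter, BatchKey, RandFn, RawResponse, reverse_map


class StringAdapter(Adapter):
    name = "STRING"
    dialect = "API"
    subject_namespace = "STRING"

    def build_request(self, batch: Sequence[BatchKey]):
        ids = "%0d".join(acc for _, acc in batch)
        return self._request(batch, f"network?identifiers={ids}&species=9606")

    def parse_response(self, response: RawResponse, batch: Sequence[BatchKey],
                       metadata_ref: str = "") -> list[AnnotationRow]:
        to_canonical = reverse_map(batch)
        try:
            doc = json.loads(response.body)
        except json.JSONDecodeError as exc:
            raise SchemaDriftError(f"STRING: body is not valid JSON ({exc})") from exc
        if not isinstance(doc, list):
            raise SchemaDriftError("STRING: expected a top-level JSON array")
        rows: list[AnnotationRow] = []
        for i, link in enumerate(doc):
            for f in ("stringId_A", "stringId_B", "score"):
                if f not in link:
                    raise SchemaDriftError(f"STRING: element [{i}] lacks field {f!r}")
            a = to_canonical.get(link["stringId_A"])
            b = to_canonical.get(link["stringId_B"])
            if a is None or b is None:
                continue
            rows.append(
                AnnotationRow(
                    anchor_key=a,
                    subject_key=a,
                    subject_type="gene",
                    relation="interacts_with",
                    object_key=b,
                    object_type="gene",
                    edge_attributes={"score": float(link["score"])},
                    source_field_map={"score": "score"},
                    metadata_ref=metadata_ref,
                )
            )
        return rows

    def fixture_response(self, request, rand: RandFn, density: float) -> str:
        accs = list(request.source_accessions)
        links = []
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                lo, hi = sorted((a, b))
                if rand("pair", lo, hi) < density:
                    links.append(
                        {
                            "stringId_A": a,
                            "stringId_B": b,
                            "preferredName_A": a.rsplit(".", 1)[-1],
                            "preferredName_B": b.rsplit(".", 1)[-1],
                            "score": round(0.4 + 0.6 * rand("pair", lo, hi, "score"), 3),
                        }
                    )
        return json.dumps(links, sort_keys=True)
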