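"""Concrete source adapters and their golden-fixture self-tests.

Five sources ship with concrete query builders and parsers — DisGeNET and
STRING and MINERVA (REST), OpenTargets (GraphQL), Bgee (SPARQL) — so every
query dialect in the catalog has at least one exercised implementation.
Each adapter is frozen against a recorded fixture under
``fixtures/<source>/`` (request payload, response body, expected rows);
:func:`adapter_selftest` replays the fixture and reports field-level
diffs, the offline analogue of scheduled per-annotator integration tests
that catch upstream schema drift.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from ..catalog import AnnotationRow
from ..errors import UnsupportedSourceError
from .base import Adapter, BatchKey, RawResponse, SourceRequest
from .bgee import BgeeAdapter
from .disgenet import DisgenetAdapter
from .minerva import MinervaAdapter
from .opentargets import OpenTargetsAdapter
from .stringdb import StringAdapter

_ADAPTERS: dict[str, Adapter] = {
    a.name: a
    for a in (
        DisgenetAdapter(),
        OpenTargetsAdapter(),
        MinervaAdapter(),
        StringAdapter(),
        BgeeAdapter(),
    )
}

CONCRETE_SOURCES = tuple(sorted(_ADAPTERS))

_ROW_FIELDS = (
    "anchor_key",
    "subject_key",
    "subject_type",
    "relation",
    "object_key",
    "object_type",
    "subject_attributes",
    "object_attributes",
    "edge_attributes",
    "source_field_map",
)


def get_adapter(source_name: str) -> Adapter:
    try:
        return _ADAPTERS[source_name]
    except KeyError:
        raise UnsupportedSourceError(
            f"no concrete adapter for source {source_name!r}; "
            f"available: {', '.join(CONCRETE_SOURCES)}"
        ) from None


def build_request(source_name: str, batch: Sequence[BatchKey]) -> SourceRequest:
    return get_adapter(source_name).build_request(batch)


def parse_response(
    source_name: str,
    response: RawResponse,
    batch: Sequence[BatchKey],
    metadata_ref: str = "",
) -> list[AnnotationRow]:
    return get_adapter(source_name).parse_response(response, batch, metadata_ref)


def row_to_record(row: AnnotationRow) -> dict[str, str]:
    """Flatten a row into TSV-safe strings (dicts JSON-encoded, keys sorted)."""
    out: dict[str, str] = {}
    for f in _ROW_FIELDS:
        value = getattr(row, f)
        out[f] = json.dumps(value, sort_keys=True) if isinstance(value, dict) else str(value)
    return out


def rows_to_tsv(rows: Sequence[AnnotationRow]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_ROW_FIELDS, delimiter="\t", lineterminator="\n")
    writer.writeheader()
    for row in sorted(rows, key=lambda r: (r.subject_key, r.relation, r.object_key)):
        writer.writerow(row_to_record(row))
    return buf.getvalue()


@dataclass
class SelfTestReport:
    """Result of replaying one source's golden fixture."""

    source_name: str
    passed: bool
    diffs: list[str] = field(default_factory=list)


def _fixture_dir(source_name: str):
    safe = source_name.lower().replace(" ", "_").replace(":", "")
    return resources.files(__package__) / "fixtures" / safe


def load_fixture_batch(source_name: str) -> list[BatchKey]:
    text = (_fixture_dir(source_name) / "batch.tsv").read_text(encoding="utf-8")
    return [tuple(line.split("\t")) for line in text.splitlines() if line.strip()]


def load_fixture_response(source_name: str) -> RawResponse:
    body = (_fixture_dir(source_name) / "response.body").read_text(encoding="utf-8")
    return RawResponse(source_name=source_name, body=body, status=200)


def adapter_selftest(source_name: str, response: RawResponse | None = None) -> SelfTestReport:
    """Replay build_request + parse_response against the bundled fixture.

    ``response`` may be overridden (e.g. with a mutated body) to verify
    that drift is detected; failures are report content, never exceptions.
    """
    adapter = get_adapter(source_name)  # raises for non-concrete sources
    fixture = _fixture_dir(source_name)
    batch = load_fixture_batch(source_name)
    diffs: list[str] = []

    expected_payload = (fixture / "request.txt").read_text(encoding="utf-8")
    built = adapter.build_request(batch)
    if built.payload != expected_payload:
        diffs.append("request payload differs from golden request.txt")

    if response is None:
        response = load_fixture_response(source_name)
    try:
        rows = adapter.parse_response(response, batch)
    except Exception as exc:
        diffs.append(f"parse failed: {type(exc).__name__}: {exc}")
        return SelfTestReport(source_name, passed=False, diffs=diffs)

    expected_text = (fixture / "expected_rows.tsv").read_text(encoding="utf-8")
    expected = list(csv.DictReader(io.StringIO(expected_text), delimiter="\t"))
    actual = list(
        csv.DictReader(io.StringIO(rows_to_tsv(rows)), delimiter="\t")
    )
    if len(expected) != len(actual):
        diffs.append(f"row count {len(actual)} != expected {len(expected)}")
    for i, (e, a) in enumerate(zip(expected, actual)):
        for f in _ROW_FIELDS:
            if e.get(f, "") != a.get(f, ""):
                diffs.append(f"row {i}: field {f!r}: {a.get(f)!r} != expected {e.get(f)!r}")
    return SelfTestReport(source_name, passed=not diffs, diffs=diffs)


__all__ = [
    "Adapter",
    "BatchKey",
    "CONCRETE_SOURCES",
    "RawResponse",
    "SelfTestReport",
    "SourceRequest",
    "adapter_selftest",
    "build_request",
    "get_adapter",
    "load_fixture_batch",
    "load_fixture_response",
    "parse_response",
    "rows_to_tsv",
]
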