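"""Adapter contract: query builder + response parser per data source.

An adapter owns everything source-specific: the namespace the source
expects subjects in, the request payload syntax (REST query string,
GraphQL document, or SPARQL query), the response shape, and the
translation of response identifiers back to canonical keys. The transport
that actually executes a :class:`SourceRequest` is injected, so adapters
are fully testable offline against recorded or synthesized responses.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

from ..catalog import AnnotationRow, SourceFailure
from ..harmonize import HarmonizedTable
from ..vocab import split_key

#: Deterministic pseudo-random helper handed to fixture synthesis:
#: maps a tuple of string parts to a float in [0, 1).
RandFn = Callable[..., float]

#: One batch element: (canonical key, accession in the source's namespace).
BatchKey = tuple[str, str]


@dataclass(frozen=True)
class SourceRequest:
    """A fully built query for one source and one entity batch."""

    source_name: str
    dialect: str
    payload: str
    entity_batch: tuple[str, ...]          # canonical keys
    source_accessions: tuple[str, ...]     # same order, source namespace

    def __post_init__(self) -> None:
        if len(self.entity_batch) != len(self.source_accessions):
            raise ValueError("entity_batch and source_accessions must align")


@dataclass(frozen=True)
class RawResponse:
    """Verbatim response body and status from a transport."""

    source_name: str
    body: str
    status: int


class Adapter(ABC):
    """Base class for concrete source adapters."""

    name: str
    dialect: str
    #: Namespace subjects must be expressed in for this source's queries.
    subject_namespace: str

    def translate_batch(
        self, table: HarmonizedTable
    ) -> tuple[list[BatchKey], list[SourceFailure]]:
        """Translate harmonized rows into this source's namespace.

        Rows whose canonical key already lies in the subject namespace pass
        through; otherwise the cross-references are consulted. A row with
        no usable cross-reference is skipped with an explicit failure
        record, never silently dropped.
        """
        keys: list[BatchKey] = []
        skips: list[SourceFailure] = []
        ns = self.subject_namespace.upper()
        for row in table.rows:
            row_ns, acc = split_key(row.canonical_key)
            if row_ns == ns:
                keys.append((row.canonical_key, acc))
                continue
            xrefs = row.cross_references.get(ns, ())
            if xrefs:
                keys.append((row.canonical_key, xrefs[0]))
            else:
                skips.append(
                    SourceFailure(
                        self.name,
                        "MissingCrossReference",
                        f"{row.canonical_key} has no {ns} cross-reference",
                    )
                )
        return keys, skips

    @abstractmethod
    def build_request(self, batch: Sequence[BatchKey]) -> SourceRequest:
        """Build a deterministic request whose payload mentions every
        accession in the batch exactly once, in input order."""

    @abstractmethod
    def parse_response(
        self,
        response: RawResponse,
        batch: Sequence[BatchKey],
        metadata_ref: str = "",
    ) -> list[AnnotationRow]:
        """Parse a successful response into annotation rows.

        Raises :class:`~biokgraph.errors.SchemaDriftError` naming the first
        offending path when the body does not match the expected shape."""

    @abstractmethod
    def fixture_response(
        self, request: SourceRequest, rand: RandFn, density: float
    ) -> str:
        """Synthesize a syntactically valid response body for this source.

        Each (entity, candidate object) pair is included iff
        ``rand(entity_accession, object_id) < density``; all numeric
        attributes are derived from ``rand`` as well, so identical inputs
        always yield byte-identical bodies."""

    def _request(self, batch: Sequence[BatchKey], payload: str) -> SourceRequest:
        if not batch:
            raise ValueError(f"{self.name}: batch must be non-empty")
        return SourceRequest(
            source_name=self.name,
            dialect=self.dialect,
            payload=payload,
            entity_batch=tuple(k for k, _ in batch),
            source_accessions=tuple(a for _, a in batch),
        )


def reverse_map(batch: Sequence[BatchKey]) -> dict[str, str]:
    """Accession-in-source-namespace → canonical key."""
    return {acc: key for key, acc in batch}
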