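"""Input parsing and identifier harmonization.

Three input kinds are supported: a plain gene/protein list, a plain
metabolite/compound list, and a differential-expression-analysis (DEA)
result table. DEA rows are gene identifiers that additionally carry an
effect size (log2 fold-change) and a significance value, preserved so the
graph can be enriched with experimental context.

Harmonization maps every input identifier onto a canonical namespace
(Entrez for genes, PubChem for compounds by default) through a mapping
table in the style of a BridgeDb identifier-mapping service: rows of
(source namespace, source id, target namespace, target id). All reachable
cross-references are retained on the harmonized row so that downstream
source adapters can translate to whatever namespace each source expects.
"""

from __future__ import annotations

import csv
import hashlib
import io
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .errors import (
    ConfigurationError,
    InputParseError,
    MappingFormatError,
    MergeConflictError,
    SchemaError,
    UnsupportedKindError,
)
from .vocab import make_key

INPUT_KINDS = ("gene_list", "metabolite_list", "dea_table")

#: Default DEA column names; overridable through ``column_map``.
DEA_COLUMNS = {"identifier": "identifier", "effect": "log2fc", "significance": "p_value"}

MAPPING_COLUMNS = ("source_namespace", "source_id", "target_namespace", "target_id")


@dataclass(frozen=True)
class DeaStats:
    """Differential-expression statistics attached to one input gene."""

    effect_size: float
    significance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.significance <= 1.0:
            raise InputParseError(
                f"significance {self.significance!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class InputRecord:
    """One input entity as supplied by the user, before mapping."""

    raw_identifier: str
    entity_kind: str
    declared_namespace: str | None = None
    dea_stats: DeaStats | None = None

    def __post_init__(self) -> None:
        if not self.raw_identifier.strip():
            raise InputParseError("empty identifier")

    @property
    def accession(self) -> str:
        """Identifier without a declared namespace prefix."""
        if self.declared_namespace is not None:
            return self.raw_identifier.split(":", 1)[1]
        return self.raw_identifier


@dataclass(frozen=True)
class IdentifierMapping:
    """One directed identifier correspondence from a mapping source."""

    source_namespace: str
    source_id: str
    target_namespace: str
    target_id: str

    def __post_init__(self) -> None:
        for f in (self.source_namespace, self.source_id, self.target_namespace, self.target_id):
            if not f:
                raise MappingFormatError("mapping fields must be non-empty")


@dataclass
class HarmonizedRow:
    """One harmonized entity: canonical key plus retained cross-references."""

    canonical_key: str
    original: InputRecord
    cross_references: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class HarmonizedTable:
    """Mapped rows, unmapped leftovers, and the mapping provenance string."""

    rows: list[HarmonizedRow]
    unmapped: list[InputRecord]
    mapping_provenance: str

    def keys(self) -> list[str]:
        return [r.canonical_key for r in self.rows]

    def row(self, canonical_key: str) -> HarmonizedRow:
        for r in self.rows:
            if r.canonical_key == canonical_key:
                return r
        raise KeyError(canonical_key)


def _token_to_record(token: str, entity_kind: str, dea: DeaStats | None = None) -> InputRecord:
    token = token.strip()
    declared = None
    if ":" in token:
        prefix = token.split(":", 1)[0]
        if prefix:
            declared = prefix.upper()
    return InputRecord(
        raw_identifier=token,
        entity_kind=entity_kind,
        declared_namespace=declared,
        dea_stats=dea,
    )


def _sniff_delimiter(text: str) -> str:
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    return "\t" if "\t" in first else ","


def parse_input(
    raw: str,
    input_kind: str,
    column_map: Mapping[str, str] | None = None,
) -> list[InputRecord]:
    """Parse text input into :class:`InputRecord` objects.

    ``gene_list`` / ``metabolite_list`` inputs are line-oriented (one
    identifier per line, ``NAMESPACE:accession`` prefixes recognized);
    ``dea_table`` input is a delimited table whose identifier, effect and
    significance columns default to ``identifier``, ``log2fc``, ``p_value``.

    Order is preserved and duplicates are retained; de-duplication happens
    at mapping time.
    """
    if input_kind not in INPUT_KINDS:
        raise UnsupportedKindError(
            f"unknown input kind {input_kind!r}; expected one of {INPUT_KINDS}"
        )

    if input_kind in ("gene_list", "metabolite_list"):
        kind = "gene" if input_kind == "gene_list" else "metabolite"
        records = []
        for line in raw.splitlines():
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            records.append(_token_to_record(token, kind))
        return records

    # DEA table
    names = dict(DEA_COLUMNS)
    if column_map:
        names.update(column_map)
    if not raw.strip():
        return []
    reader = csv.DictReader(io.StringIO(raw), delimiter=_sniff_delimiter(raw))
    header = reader.fieldnames or []
    for role in ("identifier", "effect", "significance"):
        if names[role] not in header:
            raise SchemaError(
                f"DEA table is missing column {names[role]!r} (role: {role}); "
                f"found columns {header}"
            )
    records = []
    for i, row in enumerate(reader, start=2):  # 1-based, line 1 is the header
        token = (row[names["identifier"]] or "").strip()
        if not token:
            continue
        try:
            effect = float(row[names["effect"]])
            signif = float(row[names["significance"]])
            if math.isnan(effect) or math.isnan(signif):
                raise ValueError("NaN")
        except (TypeError, ValueError) as exc:
            raise InputParseError(
                f"row {i}: non-numeric effect/significance value "
                f"({row[names['effect']]!r}, {row[names['significance']]!r})"
            ) from exc
        records.append(_token_to_record(token, "gene", DeaStats(effect, signif)))
    return records


def _lookup(
    mappings_by_source: Mapping[tuple[str | None, str], list[IdentifierMapping]],
    namespace: str | None,
    accession: str,
) -> list[IdentifierMapping]:
    """Mappings whose source matches; namespace-less inputs match any source namespace."""
    if namespace is not None:
        return mappings_by_source.get((namespace, accession), [])
    hits: list[IdentifierMapping] = []
    for (_ns, acc), ms in mappings_by_source.items():
        if acc == accession:
            hits.extend(ms)
    return hits


def map_identifiers(
    records: Sequence[InputRecord],
    mappings: Iterable[IdentifierMapping],
    target_namespace_policy: Mapping[str, str] | None = None,
    *,
    hub_namespace: str | None = None,
    mapping_provenance: str = "in-memory mapping table",
) -> HarmonizedTable:
    """Map input records onto canonical namespaces.

    A record maps iff some chain reaches the target namespace for its
    entity kind: either it is already expressed in that namespace, a direct
    mapping row reaches it, or (when ``hub_namespace`` is set) a single
    pivot hop source→hub→target does. Deeper transitive closure is not
    followed. When several target accessions are reachable, the
    lexicographically smallest becomes the canonical key and the rest are
    kept as cross-references. Distinct input records landing on one
    canonical key merge into one row; conflicting DEA statistics on a merge
    raise :class:`MergeConflictError` rather than silently averaging.
    """
    from .vocab import DEFAULT_NAMESPACE_POLICY

    policy = {k: v.upper() for k, v in (target_namespace_policy or DEFAULT_NAMESPACE_POLICY).items()}
    for kind in {r.entity_kind for r in records}:
        if kind not in policy:
            raise ConfigurationError(f"no target namespace configured for entity kind {kind!r}")

    by_source: dict[tuple[str | None, str], list[IdentifierMapping]] = {}
    for m in mappings:
        by_source.setdefault((m.source_namespace.upper(), m.source_id), []).append(m)

    rows: dict[str, HarmonizedRow] = {}
    order: list[str] = []
    unmapped: list[InputRecord] = []
    seen_unmapped: set[tuple[str, str]] = set()

    for rec in records:
        target_ns = policy[rec.entity_kind]
        direct = _lookup(by_source, rec.declared_namespace, rec.accession)
        # one pivot hop through the hub namespace
        pivoted: list[IdentifierMapping] = []
        if hub_namespace is not None:
            hub = hub_namespace.upper()
            for m in direct:
                if m.target_namespace.upper() == hub:
                    pivoted.extend(_lookup(by_source, hub, m.target_id))
        reachable = direct + pivoted

        targets = sorted(
            {m.target_id for m in reachable if m.target_namespace.upper() == target_ns}
        )
        if rec.declared_namespace == target_ns:
            targets = sorted(set(targets) | {rec.accession})
        if not targets:
            dedup = (rec.raw_identifier, rec.entity_kind)
            if dedup not in seen_unmapped:
                seen_unmapped.add(dedup)
                unmapped.append(rec)
            continue

        canonical = make_key(target_ns, targets[0])
        xrefs: dict[str, set[str]] = {}
        for extra in targets[1:]:
            xrefs.setdefault(target_ns, set()).add(extra)
        for m in reachable:
            xrefs.setdefault(m.target_namespace.upper(), set()).add(m.target_id)
            xrefs.setdefault(m.source_namespace.upper(), set()).add(m.source_id)
        if rec.declared_namespace is not None:
            xrefs.setdefault(rec.declared_namespace, set()).add(rec.accession)
        xrefs.setdefault(target_ns, set()).discard(targets[0])

        if canonical in rows:
            row = rows[canonical]
            prev = row.original.dea_stats
            cur = rec.dea_stats
            if prev is not None and cur is not None and prev != cur:
                raise MergeConflictError(
                    f"canonical key {canonical} receives conflicting DEA statistics "
                    f"from inputs {row.original.raw_identifier!r} and {rec.raw_identifier!r}"
                )
            if prev is None and cur is not None:
                row.original = rec
            for ns, accs in xrefs.items():
                merged = set(row.cross_references.get(ns, ())) | accs
                if merged:
                    row.cross_references[ns] = tuple(sorted(merged))
        else:
            rows[canonical] = HarmonizedRow(
                canonical_key=canonical,
                original=rec,
                cross_references={ns: tuple(sorted(a)) for ns, a in xrefs.items() if a},
            )
            order.append(canonical)

    return HarmonizedTable(
        rows=[rows[k] for k in order],
        unmapped=unmapped,
        mapping_provenance=mapping_provenance,
    )


def load_mapping_table(
    source: str | Path | Mapping[str, str],
    fetcher: Callable[[str], str] | None = None,
) -> tuple[list[IdentifierMapping], str]:
    """Load a 4-column TSV mapping table from disk or via a transport.

    Local mode: ``source`` is a path to a tab-separated file with header
    ``source_namespace  source_id  target_namespace  target_id``; provenance
    is the file name plus a sha256 prefix. Remote mode: ``source`` is a
    descriptor mapping with ``name`` and ``url`` keys and ``fetcher`` is a
    callable returning the body; provenance is the service name plus the
    retrieval date.
    """
    if isinstance(source, Mapping):
        if fetcher is None:
            raise ConfigurationError("remote mapping source requires a fetcher")
        name = source.get("name", "remote-mapping-service")
        text = fetcher(source["url"])
        provenance = f"{name} retrieved {date.today().isoformat()}"
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
        provenance = f"{path.name} sha256:{digest[:12]}"

    lines = text.splitlines()
    if not lines:
        raise MappingFormatError("mapping file is empty (header required)")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != MAPPING_COLUMNS:
        raise MappingFormatError(
            f"mapping header {header} does not match {MAPPING_COLUMNS}"
        )
    mappings: list[IdentifierMapping] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise MappingFormatError(
                f"line {lineno}: expected 4 tab-separated columns, found {len(parts)}"
            )
        mappings.append(IdentifierMapping(*(p.strip() for p in parts)))
    return mappings, provenance


def write_unmapped_report(table: HarmonizedTable, path: str | Path) -> None:
    """Write the unmapped identifiers as a two-column TSV (identifier, reason)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("raw_identifier\treason\n")
        for rec in table.unmapped:
            fh.write(f"{rec.raw_identifier}\tno mapping chain reached the target namespace\n")
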