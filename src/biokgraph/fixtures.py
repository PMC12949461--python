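"""Deterministic synthetic transports and demo inputs for offline runs.

The fixture transport stands in for the network: for each concrete source
it synthesizes a syntactically valid response in that source's own format
(REST JSON, GraphQL data envelope, or SPARQL JSON results). Inclusion of
each (entity, candidate object) pair is decided by a deterministic
pseudo-random stream keyed on (seed, source name, entity accession), so
identical inputs always produce byte-identical responses — which is what
makes end-to-end runs reproducible and the adapter tests hermetic.

The demo input generators emulate a small differential-expression study:
``n`` synthetic gene symbols with log2 fold-changes and p-values, plus a
BridgeDb-style mapping table giving each gene its Entrez, Ensembl, HGNC
and STRING cross-references. All identifiers are synthetic.
"""

from __future__ import annotations

import hashlib
import random

from .adapters.base import RawResponse, SourceRequest
from .errors import TransportError


def _hash_float(*parts: str) -> float:
    digest = hashlib.sha256("|".join(parts).encode("utf-8")).hexdigest()
    return int(digest[:12], 16) / 16**12


class FixtureTransport:
    """Injectable transport synthesizing per-source fixture responses."""

    def __init__(self, seed: int, density: float = 0.4):
        if not 0.0 <= density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        self.seed = seed
        self.density = density
        self.source_version = f"fixture-{seed}"

    def __call__(self, request: SourceRequest) -> RawResponse:
        from . import adapters

        adapter = adapters.get_adapter(request.source_name)

        def rand(*parts: str) -> float:
            return _hash_float(str(self.seed), request.source_name, *parts)

        body = adapter.fixture_response(request, rand, self.density)
        return RawResponse(source_name=request.source_name, body=body, status=200)


class FailingTransport:
    """Wrap a transport so that chosen sources fail; others pass through."""

    def __init__(self, inner, fail_sources: set[str] | frozenset[str]):
        self.inner = inner
        self.fail_sources = set(fail_sources)
        self.source_version = getattr(inner, "source_version", "unknown")

    def __call__(self, request: SourceRequest) -> RawResponse:
        if request.source_name in self.fail_sources:
            raise TransportError(f"injected failure for {request.source_name}")
        return self.inner(request)


def fixture_fetcher(seed: int, density: float = 0.4) -> FixtureTransport:
    """The canonical way to obtain an offline transport."""
    return FixtureTransport(seed=seed, density=density)


# ---------------------------------------------------------------------------
# Demo inputs

def demo_gene_ids(n: int) -> list[dict[str, str]]:
    """Synthetic gene identifier block: symbol + four cross-references."""
    genes = []
    for i in range(1, n + 1):
        genes.append(
            {
                "symbol": f"GS{i}",
                "entrez": str(1000 + i),
                "ensembl": f"ENSG{1000000 + i:011d}",
                "string": f"9606.ENSP{1000000 + i:011d}",
            }
        )
    return genes


def demo_mapping_table_text(n: int = 10) -> str:
    """BridgeDb-style 4-column TSV covering the demo genes."""
    lines = ["source_namespace\tsource_id\ttarget_namespace\ttarget_id"]
    for g in demo_gene_ids(n):
        lines.append(f"HGNC\t{g['symbol']}\tENTREZ\t{g['entrez']}")
        lines.append(f"HGNC\t{g['symbol']}\tENSEMBL\t{g['ensembl']}")
        lines.append(f"HGNC\t{g['symbol']}\tSTRING\t{g['string']}")
        lines.append(f"ENTREZ\t{g['entrez']}\tENSEMBL\t{g['ensembl']}")
        lines.append(f"ENTREZ\t{g['entrez']}\tSTRING\t{g['string']}")
        lines.append(f"ENTREZ\t{g['entrez']}\tHGNC\t{g['symbol']}")
    return "\n".join(lines) + "\n"


def demo_dea_table_text(n: int = 10, seed: int = 0) -> str:
    """Synthetic DEA result table: identifier, log2fc, p_value.

    Effect sizes are drawn in [-3, 3] and p-values in (0, 0.05] — the shape
    of a significance-filtered differential-expression table.
    """
    rng = random.Random(seed)
    lines = ["identifier\tlog2fc\tp_value"]
    for g in demo_gene_ids(n):
        log2fc = round(rng.uniform(-3.0, 3.0), 3)
        p = round(rng.uniform(1e-6, 0.05), 6)
        lines.append(f"{g['symbol']}\t{log2fc}\t{p}")
    return "\n".join(lines) + "\n"


def demo_gene_list_text(n: int = 10) -> str:
    """Synthetic plain gene list, one symbol per line."""
    return "\n".join(g["symbol"] for g in demo_gene_ids(n)) + "\n"
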