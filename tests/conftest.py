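"""Shared fixtures: synthetic tables and fixture-driven random graphs."""

from __future__ import annotations

import logging
import random

import pytest

from biokgraph import annotate, build_graph
from biokgraph.adapters import CONCRETE_SOURCES
from biokgraph.fixtures import (
    demo_dea_table_text,
    demo_mapping_table_text,
    fixture_fetcher,
)
from biokgraph.harmonize import IdentifierMapping, map_identifiers, parse_input

# attribute-overwrite warnings are expected when sources share an edge
logging.getLogger("biokgraph.graph").setLevel(logging.ERROR)


def make_table(n_genes: int = 10, seed: int = 0):
    """Harmonized table over the synthetic DEA study."""
    records = parse_input(demo_dea_table_text(n_genes, seed), "dea_table")
    mappings = [
        IdentifierMapping(*line.split("\t"))
        for line in demo_mapping_table_text(n_genes).splitlines()[1:]
    ]
    return map_identifiers(records, mappings, mapping_provenance=f"demo-{n_genes}")


def make_graph(
    seed: int,
    n_genes: int = 4,
    density: float = 0.5,
    sources: tuple[str, ...] = ("DisGeNET", "MINERVA", "STRING"),
):
    """Graph built through the real annotate/build path on fixtures."""
    table = make_table(n_genes, seed)
    rows, metadata, _ = annotate(table, sources, fixture_fetcher(seed, density))
    return build_graph(table, rows, metadata)


def random_graph(seed: int):
    """Varied fixture-generated graph: size, density and sources all vary."""
    rng = random.Random(seed)
    n_genes = rng.randint(2, 6)
    density = rng.uniform(0.2, 0.8)
    k = rng.randint(1, len(CONCRETE_SOURCES))
    sources = tuple(rng.sample(sorted(CONCRETE_SOURCES), k))
    return make_graph(seed, n_genes, density, sources)


@pytest.fixture
def demo_table():
    return make_table()


@pytest.fixture
def small_graph():
    return make_graph(seed=11, n_genes=3)
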