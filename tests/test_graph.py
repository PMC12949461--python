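"""Graph construction, merging semantics, context nodes, validation."""

from __future__ import annotations

import random

import pytest

from biokgraph import add_context_node, build_graph, validate_graph
from biokgraph.catalog import AnnotationRow, QueryMetadata
from biokgraph.errors import IntegrityError, NodeTypeConflictError
from biokgraph.graph import GraphEdge
from biokgraph.harmonize import map_identifiers, parse_input
from biokgraph.vocab import NODE_TYPES, RELATIONS
from conftest import make_graph, make_table, random_graph


def gene_table(n=2):
    ids = "\n".join(f"ENTREZ:{1000+i}" for i in range(1, n + 1))
    return map_identifiers(parse_input(ids, "gene_list"), [])


def meta(source, mid=None):
    return QueryMetadata(
        metadata_id=mid or f"{source}#0",
        source_name=source,
        source_version="v1",
        retrieval_date="2026-01-01",
        input_count=2,
        result_count=1,
        duration_seconds=0.0,
    )


def gd_row(gene, disease, metadata_ref):
    return AnnotationRow(
        anchor_key=gene,
        subject_key=gene,
        subject_type="gene",
        relation="associated_with",
        object_key=disease,
        object_type="disease",
        metadata_ref=metadata_ref,
    )


class TestBuildGraph:
    def test_empty_inputs_empty_graph(self):
        g = build_graph(map_identifiers([], []), [], [])
        assert g.node_count == 0 and g.edge_count == 0

    def test_distinct_triples_two_edges(self):
        table = gene_table(2)
        k1, k2 = table.keys()
        rows = [gd_row(k1, "UMLS:C1", "A#0"), gd_row(k2, "UMLS:C1", "B#0")]
        g = build_graph(table, rows, [meta("A", "A#0"), meta("B", "B#0")])
        assert g.node_count == 3  # 2 genes + 1 shared disease
        assert g.edge_count == 2
        assert all(len(e.provenance) == 1 for e in g.edges.values())

    def test_same_triple_merges_with_two_provenance_entries(self):
        table = gene_table(1)
        (k1,) = table.keys()
        rows = [gd_row(k1, "UMLS:C1", "A#0"), gd_row(k1, "UMLS:C1", "B#0")]
        g = build_graph(table, rows, [meta("A", "A#0"), meta("B", "B#0")])
        assert g.edge_count == 1
        (edge,) = g.edges.values()
        assert {p[0] for p in edge.provenance} == {"A", "B"}

    def test_unannotated_entities_still_become_nodes(self):
        table = gene_table(3)
        g = build_graph(table, [], [])
        assert g.node_count == 3 and g.edge_count == 0
        assert all(n.attributes["from_input"] for n in g.nodes.values())

    def test_dea_stats_copied_onto_gene_nodes(self):
        table = make_table(3, seed=0)
        g = build_graph(table, [], [])
        for row in table.rows:
            node = g.nodes[row.canonical_key]
            assert node.attributes["effect_size"] == row.original.dea_stats.effect_size

    def test_build_deterministic(self):
        g1 = make_graph(seed=4)
        g2 = make_graph(seed=4)
        assert g1.structural_signature() == g2.structural_signature()

    def test_merge_commutative_over_row_order(self):
        table = make_table(4, seed=2)
        from biokgraph import annotate
        from biokgraph.fixtures import fixture_fetcher

        rows, metadata, _ = annotate(
            table, ("DisGeNET", "STRING", "MINERVA"), fixture_fetcher(2, 0.6)
        )
        shuffled = list(rows)
        random.Random(0).shuffle(shuffled)
        g1 = build_graph(table, rows, metadata)
        g2 = build_graph(table, shuffled, metadata)
        assert g1.structural_signature() == g2.structural_signature()

    def test_unknown_anchor_is_integrity_error(self):
        table = gene_table(1)
        with pytest.raises(IntegrityError, match="ENTREZ:9999"):
            build_graph(table, [gd_row("ENTREZ:9999", "UMLS:C1", "A#0")], [meta("A")])

    def test_node_type_conflict_detected(self):
        table = gene_table(1)
        (k1,) = table.keys()
        rows = [
            gd_row(k1, "UMLS:C1", "A#0"),
            AnnotationRow(
                anchor_key=k1, subject_key=k1, subject_type="gene",
                relation="part_of", object_key="UMLS:C1", object_type="pathway",
                metadata_ref="A#0",
            ),
        ]
        with pytest.raises(NodeTypeConflictError, match="UMLS:C1"):
            build_graph(table, rows, [meta("A")])


class TestContextNode:
    def test_add_with_three_links(self):
        g = build_graph(gene_table(3), [], [])
        genes = sorted(g.nodes)
        add_context_node(
            g, "UMLS:C5433293", "disease", "Long COVID-19",
            [(k, "associated_with", "literature") for k in genes],
        )
        assert g.node_count == 4
        assert g.edge_count == 3
        edge = g.edges[(genes[0], "associated_with", "UMLS:C5433293")]
        assert edge.provenance[0][0] == "literature"

    def test_add_with_empty_links(self):
        g = build_graph(gene_table(1), [], [])
        add_context_node(g, "UMLS:C5433293", "disease", "Long COVID-19")
        assert g.node_count == 2 and g.edge_count == 0

    def test_re_adding_merges(self):
        g = build_graph(gene_table(1), [], [])
        add_context_node(g, "UMLS:C5433293", "disease", "Long COVID-19")
        add_context_node(g, "UMLS:C5433293", "disease", "Long COVID-19")
        assert g.node_count == 2

    def test_link_to_missing_entity(self):
        g = build_graph(gene_table(1), [], [])
        with pytest.raises(IntegrityError, match="ENTREZ:404"):
            add_context_node(
                g, "UMLS:C5433293", "disease", "x",
                [("ENTREZ:404", "associated_with", "t")],
            )


class TestValidateGraph:
    def test_valid_toy_graph_clean(self, small_graph):
        assert validate_graph(small_graph) == []

    def test_empty_provenance_flagged(self, small_graph):
        edge = next(iter(small_graph.edges.values()))
        edge.provenance.clear()
        violations = validate_graph(small_graph)
        assert len(violations) == 1 and "provenance" in violations[0]

    def test_dangling_endpoint_flagged_by_key(self, small_graph):
        ghost = GraphEdge("ENTREZ:404", "associated_with", next(iter(small_graph.nodes)),
                          provenance=[("x", "v", "2026-01-01")])
        small_graph.edges[ghost.key] = ghost
        violations = validate_graph(small_graph)
        assert any("ENTREZ:404" in v for v in violations)

    def test_self_loop_only_for_interactions(self, small_graph):
        key = next(iter(small_graph.nodes))
        bad = GraphEdge(key, "treats", key, provenance=[("x", "v", "2026-01-01")])
        small_graph.edges[bad.key] = bad
        assert any("self-loop" in v for v in validate_graph(small_graph))


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_closed_vocabularies_on_fixture_graphs(self, seed):
        g = random_graph(seed)
        assert {n.node_type for n in g.nodes.values()} <= NODE_TYPES
        assert {e.relation for e in g.edges.values()} <= RELATIONS

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_of_nodes_and_edges(self, seed):
        from biokgraph import annotate
        from biokgraph.fixtures import fixture_fetcher

        table = make_table(4, seed)
        rows, metadata, _ = annotate(
            table, ("DisGeNET", "OpenTargets", "STRING"), fixture_fetcher(seed, 0.5)
        )
        g = build_graph(table, rows, metadata)
        table_keys = set(table.keys())
        endpoint_keys = {r.subject_key for r in rows} | {r.object_key for r in rows}
        assert g.node_count == len(table_keys | endpoint_keys)
        assert g.edge_count == len(
            {(r.subject_key, r.relation, r.object_key) for r in rows}
        )
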