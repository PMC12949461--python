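"""Summaries, subgraph extraction, and training-triple export."""

from __future__ import annotations

import pytest

from biokgraph import (
    PropertyGraph,
    export_training_triples,
    extract_subgraph,
    plot_summary,
    summarize,
    validate_graph,
)
from biokgraph.analyze import GraphSummary
from biokgraph.errors import BiokgraphError, InfeasibleSamplingError
from biokgraph.graph import GraphEdge, GraphNode
from conftest import random_graph

PROV = [("src", "v1", "2026-01-01")]


def chain_graph(n=6):
    """Path graph: gene_0 —interacts_with→ gene_1 → ... → gene_{n-1}."""
    g = PropertyGraph()
    for i in range(n):
        g.nodes[f"ENTREZ:{i}"] = GraphNode(f"ENTREZ:{i}", "gene", f"g{i}")
    for i in range(n - 1):
        key = (f"ENTREZ:{i}", "interacts_with", f"ENTREZ:{i+1}")
        g.edges[key] = GraphEdge(*key, provenance=list(PROV))
    return g


def bfs_oracle(graph, anchors, hops):
    """Brute-force frontier expansion over undirected adjacency."""
    seen = set(anchors)
    frontier = set(anchors)
    for _ in range(hops):
        nxt = set()
        for e in graph.edges.values():
            if e.subject_key in frontier:
                nxt.add(e.object_key)
            if e.object_key in frontier:
                nxt.add(e.subject_key)
        frontier = nxt - seen
        seen |= frontier
    return seen


class TestSummarize:
    def test_empty_graph_all_zero(self):
        s = summarize(PropertyGraph())
        assert s.node_count_total == 0 and s.edge_count_total == 0
        assert s.nodes_by_type == {} and s.edges_by_source == {}

    def test_multi_source_edge_counts_once_per_source(self):
        g = chain_graph(3)
        first = next(iter(g.edges.values()))
        first.provenance.append(("other", "v2", "2026-01-02"))
        s = summarize(g)
        assert s.edge_count_total == 2
        assert sum(s.edges_by_source.values()) == 3

    def test_unannotated_inputs_counted(self):
        g = chain_graph(3)
        for node in g.nodes.values():
            node.attributes["from_input"] = True
        g.nodes["ENTREZ:99"] = GraphNode("ENTREZ:99", "gene", "lonely",
                                         attributes={"from_input": True})
        assert summarize(g).unannotated_input_entities == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_count_invariants_on_fixture_graphs(self, seed):
        g = random_graph(seed)
        s = summarize(g)
        assert sum(s.nodes_by_type.values()) == s.node_count_total == g.node_count
        assert sum(s.edges_by_relation.values()) == s.edge_count_total == g.edge_count
        assert sum(s.edges_by_source.values()) >= s.edge_count_total

    def test_tsv_and_json_exports(self):
        s = summarize(chain_graph(2))
        assert "edges_by_relation\tinteracts_with\t1" in s.to_tsv()
        assert '"edge_count_total": 1' in s.to_json()


class TestExtractSubgraph:
    def test_hops_zero_single_node(self):
        g = chain_graph()
        sub = extract_subgraph(g, {"ENTREZ:0"}, 0)
        assert sub.node_count == 1 and sub.edge_count == 0

    def test_path_graph_two_hops(self):
        g = chain_graph(6)
        sub = extract_subgraph(g, {"ENTREZ:0"}, 2)
        assert sub.node_count == 3 and sub.edge_count == 2

    def test_unknown_anchor(self):
        with pytest.raises(BiokgraphError, match="ENTREZ:404"):
            extract_subgraph(chain_graph(), {"ENTREZ:404"}, 1)

    def test_relation_filter_annihilation(self):
        g = chain_graph(4)
        sub = extract_subgraph(g, {"ENTREZ:0"}, 2, relation_filter=set())
        assert sub.node_count == 3 and sub.edge_count == 0

    def test_node_type_filter_keeps_anchor(self, small_graph):
        anchor = next(iter(small_graph.nodes))
        sub = extract_subgraph(small_graph, {anchor}, 1, node_type_filter={"disease"})
        assert anchor in sub.nodes
        others = {k for k in sub.nodes if k != anchor}
        assert all(sub.nodes[k].node_type == "disease" for k in others)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("hops", [0, 1, 2, 3])
    def test_matches_bfs_oracle(self, seed, hops):
        g = random_graph(seed)
        anchor = sorted(g.nodes)[0]
        sub = extract_subgraph(g, {anchor}, hops)
        assert set(sub.nodes) == bfs_oracle(g, {anchor}, hops)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_hops_and_valid(self, seed):
        g = random_graph(seed)
        anchor = sorted(g.nodes)[0]
        previous: set = set()
        for hops in range(4):
            sub = extract_subgraph(g, {anchor}, hops)
            assert previous <= set(sub.nodes)
            assert validate_graph(sub) == []
            previous = set(sub.nodes)


class TestTrainingTriples:
    def test_ratio_zero_all_positive(self, small_graph):
        df = export_training_triples(small_graph, 0.0, seed=1)
        assert len(df) == small_graph.edge_count
        assert (df["label"] == 1).all()

    def test_deterministic_for_fixed_seed(self, small_graph):
        a = export_training_triples(small_graph, 0.5, seed=42)
        b = export_training_triples(small_graph, 0.5, seed=42)
        assert a.equals(b)

    def test_exhaustive_negatives_match_enumeration(self):
        g = PropertyGraph()
        g.nodes["ENTREZ:1"] = GraphNode("ENTREZ:1", "gene", "g1")
        g.nodes["ENTREZ:2"] = GraphNode("ENTREZ:2", "gene", "g2")
        g.nodes["UMLS:C1"] = GraphNode("UMLS:C1", "disease", "d1")
        g.edges[("ENTREZ:1", "interacts_with", "ENTREZ:2")] = GraphEdge(
            "ENTREZ:1", "interacts_with", "ENTREZ:2", provenance=list(PROV)
        )
        # type-compatible combos: 4 gene-gene interactions (self-loops allowed)
        # + 2 gene-disease associations, minus the 1 positive = 5 free
        df = export_training_triples(g, 5.0, seed=0)
        negatives = {tuple(r) for r in df[df.label == 0][["head", "relation", "tail"]].values}
        expected = {
            ("ENTREZ:1", "interacts_with", "ENTREZ:1"),
            ("ENTREZ:2", "interacts_with", "ENTREZ:1"),
            ("ENTREZ:2", "interacts_with", "ENTREZ:2"),
            ("ENTREZ:1", "associated_with", "UMLS:C1"),
            ("ENTREZ:2", "associated_with", "UMLS:C1"),
        }
        assert negatives == expected
        with pytest.raises(InfeasibleSamplingError):
            export_training_triples(g, 6.0, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_negative_disjoint(self, seed):
        g = random_graph(seed)
        df = export_training_triples(g, 1.0, seed=seed)
        pos = {tuple(r) for r in df[df.label == 1][["head", "relation", "tail"]].values}
        neg = {tuple(r) for r in df[df.label == 0][["head", "relation", "tail"]].values}
        assert pos.isdisjoint(neg)
        assert len(neg) == len(pos)


class TestPlots:
    def test_files_written_nonempty(self, tmp_path, small_graph):
        paths = plot_summary(summarize(small_graph), tmp_path)
        assert len(paths) == 3
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)

    def test_empty_summary_still_plots(self, tmp_path):
        paths = plot_summary(GraphSummary(0, 0), tmp_path)
        assert all(p.exists() for p in paths)

    def test_unwritable_path_raises(self, tmp_path):
        blocker = tmp_path / "file"
        blocker.write_text("x")
        with pytest.raises(OSError):
            plot_summary(GraphSummary(0, 0), blocker)
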