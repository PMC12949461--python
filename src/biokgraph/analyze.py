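"""Graph summaries, context subgraphs, and training-set preparation.

Summaries count nodes by type, edges by relation, and edges by
contributing source (an edge with multi-source provenance counts once per
source, so the per-source column sums to at least the edge total).
Subgraph extraction expands an undirected neighborhood around anchor
nodes — the tissue/context use case — while preserving edge direction and
provenance in the result. Training-triple export turns the graph into a
labelled link-prediction table with uniform type-compatible negative
sampling.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .catalog import default_catalog
from .errors import BiokgraphError, InfeasibleSamplingError
from .graph import GraphEdge, GraphNode, PropertyGraph


@dataclass
class GraphSummary:
    node_count_total: int
    edge_count_total: int
    nodes_by_type: dict[str, int] = field(default_factory=dict)
    edges_by_relation: dict[str, int] = field(default_factory=dict)
    edges_by_source: dict[str, int] = field(default_factory=dict)
    unannotated_input_entities: int = 0
    #: Publication/patent counts per entity; populated only when a
    #: literature annotator contributed (none ships concretely).
    literature_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["section\tkey\tvalue"]
        lines.append(f"totals\tnodes\t{self.node_count_total}")
        lines.append(f"totals\tedges\t{self.edge_count_total}")
        lines.append(f"totals\tunannotated_input_entities\t{self.unannotated_input_entities}")
        for section, counts in (
            ("nodes_by_type", self.nodes_by_type),
            ("edges_by_relation", self.edges_by_relation),
            ("edges_by_source", self.edges_by_source),
        ):
            for k in sorted(counts):
                lines.append(f"{section}\t{k}\t{counts[k]}")
        return "\n".join(lines) + "\n"


def summarize(graph: PropertyGraph) -> GraphSummary:
    """Compute the standard count summary of a property graph."""
    nodes_by_type = Counter(n.node_type for n in graph.nodes.values())
    edges_by_relation = Counter(e.relation for e in graph.edges.values())
    edges_by_source: Counter[str] = Counter()
    touched: set[str] = set()
    for edge in graph.edges.values():
        for source in {p[0] for p in edge.provenance}:
            edges_by_source[source] += 1
        touched.add(edge.subject_key)
        touched.add(edge.object_key)
    unannotated = sum(
        1
        for n in graph.nodes.values()
        if n.attributes.get("from_input") and n.key not in touched
    )
    return GraphSummary(
        node_count_total=graph.node_count,
        edge_count_total=graph.edge_count,
        nodes_by_type=dict(sorted(nodes_by_type.items())),
        edges_by_relation=dict(sorted(edges_by_relation.items())),
        edges_by_source=dict(sorted(edges_by_source.items())),
        unannotated_input_entities=unannotated,
    )


def extract_subgraph(
    graph: PropertyGraph,
    anchors: set[str],
    hops: int,
    node_type_filter: set[str] | None = None,
    relation_filter: set[str] | None = None,
) -> PropertyGraph:
    """Induced subgraph within ``hops`` undirected steps of the anchors.

    Type and relation filters apply after expansion: anchor nodes are
    always kept, other nodes must pass the type filter, and edges must
    pass the relation filter as well as connect two kept nodes.
    """
    missing = anchors - set(graph.nodes)
    if missing:
        raise BiokgraphError(f"unknown anchor node(s): {sorted(missing)}")
    if hops < 0:
        raise ValueError("hops must be non-negative")

    undirected = nx.Graph()
    undirected.add_nodes_from(graph.nodes)
    undirected.add_edges_from((e.subject_key, e.object_key) for e in graph.edges.values())
    within: set[str] = set()
    for anchor in anchors:
        lengths = nx.single_source_shortest_path_length(undirected, anchor, cutoff=hops)
        within.update(lengths)

    keep = {
        k
        for k in within
        if k in anchors
        or node_type_filter is None
        or graph.nodes[k].node_type in node_type_filter
    }
    sub = PropertyGraph(build_metadata=list(graph.build_metadata))
    for key in sorted(keep):
        n = graph.nodes[key]
        sub.nodes[key] = GraphNode(
            key=n.key, node_type=n.node_type, label=n.label,
            xrefs={ns: tuple(a) for ns, a in n.xrefs.items()},
            attributes=dict(n.attributes),
        )
    for edge in graph.sorted_edges():
        if edge.subject_key in keep and edge.object_key in keep:
            if relation_filter is not None and edge.relation not in relation_filter:
                continue
            sub.edges[edge.key] = GraphEdge(
                edge.subject_key, edge.relation, edge.object_key,
                provenance=list(edge.provenance),
                attributes=dict(edge.attributes),
            )
    return sub


def export_training_triples(
    graph: PropertyGraph,
    negative_ratio: float,
    seed: int,
) -> pd.DataFrame:
    """Labelled (head, relation, tail) table for link-prediction training.

    Positives are the graph's edges. ``floor(negative_ratio * |edges|)``
    negatives are drawn uniformly (seeded) from the type-compatible
    non-edges, where compatibility follows the catalog's edge-category
    incidence; no negative duplicates a positive.
    """
    if negative_ratio < 0:
        raise ValueError("negative_ratio must be non-negative")
    positives = [(e.subject_key, e.relation, e.object_key) for e in graph.sorted_edges()]
    n_negatives = int(negative_ratio * len(positives))

    records = [(h, r, t, 1) for h, r, t in positives]
    if n_negatives:
        incidence = set()
        for d in default_catalog():
            incidence |= d.edge_categories
        by_type: dict[str, list[str]] = {}
        for node in graph.sorted_nodes():
            by_type.setdefault(node.node_type, []).append(node.key)
        positive_set = set(positives)
        candidates = [
            (h, rel, t)
            for stype, rel, otype in sorted(incidence)
            for h in by_type.get(stype, [])
            for t in by_type.get(otype, [])
            if (h != t or rel == "interacts_with") and (h, rel, t) not in positive_set
        ]
        if n_negatives > len(candidates):
            raise InfeasibleSamplingError(
                f"requested {n_negatives} negatives but only "
                f"{len(candidates)} type-compatible non-edges exist"
            )
        rng = random.Random(seed)
        records += [(h, r, t, 0) for h, r, t in rng.sample(candidates, n_negatives)]
    return pd.DataFrame(records, columns=["head", "relation", "tail", "label"])


def plot_summary(summary: GraphSummary, output_dir: str | Path) -> list[Path]:
    """Write bar charts for the three count sections; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, counts in (
        ("nodes_by_type", summary.nodes_by_type),
        ("edges_by_relation", summary.edges_by_relation),
        ("edges_by_source", summary.edges_by_source),
    ):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        keys = sorted(counts)
        ax.bar(range(len(keys)), [counts[k] for k in keys], color="#4878a8")
        ax.set_xticks(range(len(keys)))
        ax.set_xticklabels(keys, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("count")
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        path = out / f"{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
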