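"""Input parsing and identifier-mapping behaviour."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biokgraph.errors import (
    ConfigurationError,
    InputParseError,
    MappingFormatError,
    MergeConflictError,
    SchemaError,
    UnsupportedKindError,
)
from biokgraph.harmonize import (
    IdentifierMapping,
    InputRecord,
    load_mapping_table,
    map_identifiers,
    parse_input,
)

GENES_3 = "TP53\nTNF\nIL6\n"
DEA_5 = (
    "identifier\tlog2fc\tp_value\n"
    "GS1\t1.5\t0.01\nGS2\t-0.7\t0.02\nGS3\t2.2\t0.001\n"
    "GS4\t0.3\t0.04\nGS5\t-1.1\t0.03\n"
)


class TestParseInput:
    def test_empty_gene_list(self):
        assert parse_input("", "gene_list") == []

    def test_three_gene_symbols(self):
        records = parse_input(GENES_3, "gene_list")
        assert len(records) == 3
        assert [r.raw_identifier for r in records] == ["TP53", "TNF", "IL6"]
        assert all(r.dea_stats is None for r in records)
        assert all(r.entity_kind == "gene" for r in records)

    def test_metabolite_list_kind(self):
        records = parse_input("PUBCHEM:2244\n", "metabolite_list")
        assert records[0].entity_kind == "metabolite"
        assert records[0].declared_namespace == "PUBCHEM"
        assert records[0].accession == "2244"

    def test_dea_table_five_rows(self):
        records = parse_input(DEA_5, "dea_table")
        assert len(records) == 5
        assert records[0].dea_stats.effect_size == 1.5
        assert records[0].dea_stats.significance == 0.01
        assert all(r.dea_stats is not None for r in records)

    def test_order_and_duplicates_preserved(self):
        records = parse_input("A\nB\nA\n", "gene_list")
        assert [r.raw_identifier for r in records] == ["A", "B", "A"]

    def test_unknown_kind(self):
        with pytest.raises(UnsupportedKindError):
            parse_input("x", "proteome")

    def test_missing_identifier_column_names_it(self):
        with pytest.raises(SchemaError, match="identifier"):
            parse_input("gene\tlog2fc\tp_value\nX\t1\t0.1\n", "dea_table")

    def test_non_numeric_effect_reports_row(self):
        bad = "identifier\tlog2fc\tp_value\nGS1\thigh\t0.01\n"
        with pytest.raises(InputParseError, match="row 2"):
            parse_input(bad, "dea_table")

    def test_custom_column_map(self):
        text = "id,lfc,padj\nGS1,1.0,0.01\n"
        records = parse_input(
            text, "dea_table",
            {"identifier": "id", "effect": "lfc", "significance": "padj"},
        )
        assert records[0].dea_stats.effect_size == 1.0


class TestMapIdentifiers:
    def test_no_mappings_all_unmapped(self):
        records = parse_input(GENES_3, "gene_list")
        table = map_identifiers(records, [])
        assert table.rows == []
        assert len(table.unmapped) == 3

    def test_already_canonical_identity(self):
        records = parse_input("ENTREZ:7157\nENTREZ:7124\n", "gene_list")
        table = map_identifiers(records, [])
        assert table.keys() == ["ENTREZ:7157", "ENTREZ:7124"]
        assert table.unmapped == []

    def test_four_of_five_mapped(self):
        records = parse_input("A\nB\nC\nD\nE\n", "gene_list")
        mappings = [
            IdentifierMapping("SYM", s, "ENTREZ", str(i))
            for i, s in enumerate(["A", "B", "C", "D"], start=1)
        ]
        table = map_identifiers(records, mappings)
        assert len(table.rows) == 4
        assert len(table.unmapped) == 1
        assert table.unmapped[0].raw_identifier == "E"

    def test_partition_property(self, demo_table):
        raws = {r.original.raw_identifier for r in demo_table.rows}
        raws |= {r.raw_identifier for r in demo_table.unmapped}
        assert len(raws) == 10

    def test_idempotence_on_canonical_keys(self, demo_table):
        again = map_identifiers(
            parse_input("\n".join(demo_table.keys()), "gene_list"), []
        )
        assert set(again.keys()) == set(demo_table.keys())

    def test_one_to_many_takes_lexicographic_first(self):
        mappings = [
            IdentifierMapping("SYM", "A", "ENTREZ", "9"),
            IdentifierMapping("SYM", "A", "ENTREZ", "10"),
        ]
        table = map_identifiers(parse_input("A\n", "gene_list"), mappings)
        assert table.keys() == ["ENTREZ:10"]  # "10" < "9" lexicographically
        assert "9" in table.rows[0].cross_references["ENTREZ"]

    def test_pivot_hop_through_hub(self):
        mappings = [
            IdentifierMapping("SYM", "A", "HGNC", "A1"),
            IdentifierMapping("HGNC", "A1", "ENTREZ", "42"),
        ]
        no_hub = map_identifiers(parse_input("A\n", "gene_list"), mappings)
        assert no_hub.rows == []
        with_hub = map_identifiers(
            parse_input("A\n", "gene_list"), mappings, hub_namespace="HGNC"
        )
        assert with_hub.keys() == ["ENTREZ:42"]

    def test_conflicting_dea_stats_raise(self):
        text = "identifier\tlog2fc\tp_value\nA\t1.0\t0.01\nA2\t2.0\t0.02\n"
        records = parse_input(text, "dea_table")
        mappings = [
            IdentifierMapping("SYM", "A", "ENTREZ", "1"),
            IdentifierMapping("SYM", "A2", "ENTREZ", "1"),
        ]
        with pytest.raises(MergeConflictError, match="A2"):
            map_identifiers(records, mappings)

    def test_identical_duplicates_merge_silently(self):
        text = "identifier\tlog2fc\tp_value\nA\t1.0\t0.01\nA\t1.0\t0.01\n"
        table = map_identifiers(
            parse_input(text, "dea_table"),
            [IdentifierMapping("SYM", "A", "ENTREZ", "1")],
        )
        assert len(table.rows) == 1

    def test_missing_policy_for_kind(self):
        with pytest.raises(ConfigurationError):
            map_identifiers(
                parse_input("A\n", "gene_list"), [], target_namespace_policy={"metabolite": "PUBCHEM"}
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ids=st.lists(st.sampled_from("abcdefgh"), min_size=0, max_size=20),
        mapped=st.sets(st.sampled_from("abcdefgh")),
    )
    def test_matches_brute_force_lookup_oracle(self, ids, mapped):
        """Exhaustive per-record lookup gives the same mapped/unmapped split."""
        records = [InputRecord(i, "gene") for i in ids]
        mappings = [IdentifierMapping("SYM", s, "ENTREZ", s.upper()) for s in mapped]
        table = map_identifiers(records, mappings)
        expected_mapped = sorted(
            {f"ENTREZ:{i.upper()}" for i in ids if i in mapped}
        )
        assert sorted(table.keys()) == expected_mapped
        assert {r.raw_identifier for r in table.unmapped} == {
            i for i in set(ids) if i not in mapped
        }


class TestLoadMappingTable:
    HEADER = "source_namespace\tsource_id\ttarget_namespace\ttarget_id\n"

    def test_header_only_empty(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(self.HEADER)
        mappings, _ = load_mapping_table(path)
        assert mappings == []

    def test_six_rows_with_checksum_provenance(self, tmp_path):
        body = "".join(f"SYM\tg{i}\tENTREZ\t{i}\n" for i in range(6))
        path = tmp_path / "m.tsv"
        path.write_text(self.HEADER + body)
        mappings, provenance = load_mapping_table(path)
        assert len(mappings) == 6
        assert "sha256:" in provenance and "m.tsv" in provenance

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(self.HEADER + "SYM\tg1\tENTREZ\n")
        with pytest.raises(MappingFormatError, match="line 2"):
            load_mapping_table(path)

    def test_remote_without_fetcher(self):
        with pytest.raises(ConfigurationError):
            load_mapping_table({"name": "svc", "url": "https://x"})

    def test_remote_with_fetcher(self):
        mappings, provenance = load_mapping_table(
            {"name": "svc", "url": "https://x"},
            fetcher=lambda url: self.HEADER + "SYM\tg1\tENTREZ\t1\n",
        )
        assert len(mappings) == 1
        assert "svc" in provenance
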