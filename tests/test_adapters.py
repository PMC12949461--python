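"""Adapter request building, response parsing, and golden self-tests."""

from __future__ import annotations

import json
from urllib.parse import parse_qs, urlparse

import pytest
from rdflib.plugins.sparql import prepareQuery

from biokgraph.adapters import (
    CONCRETE_SOURCES,
    RawResponse,
    adapter_selftest,
    get_adapter,
    load_fixture_batch,
    load_fixture_response,
)
from biokgraph.adapters.graphql_check import GraphQLSyntaxError, validate_graphql
from biokgraph.errors import SchemaDriftError, UnsupportedSourceError

BATCH3 = {
    "DisGeNET": [("ENTREZ:1001", "1001"), ("ENTREZ:1002", "1002"), ("ENTREZ:1003", "1003")],
    "STRING": [("ENTREZ:1001", "9606.ENSP01"), ("ENTREZ:1002", "9606.ENSP02"),
               ("ENTREZ:1003", "9606.ENSP03")],
    "MINERVA": [("ENTREZ:1001", "GS1"), ("ENTREZ:1002", "GS2"), ("ENTREZ:1003", "GS3")],
    "OpenTargets": [("ENTREZ:1001", "ENSG01"), ("ENTREZ:1002", "ENSG02"),
                    ("ENTREZ:1003", "ENSG03")],
    "Bgee": [("ENTREZ:1001", "ENSG01"), ("ENTREZ:1002", "ENSG02"),
             ("ENTREZ:1003", "ENSG03")],
}


class TestBuildRequest:
    @pytest.mark.parametrize("source", sorted(BATCH3))
    def test_payload_mentions_each_accession_once_in_order(self, source):
        batch = BATCH3[source]
        payload = get_adapter(source).build_request(batch).payload
        positions = []
        for _, acc in batch:
            assert payload.count(acc) == 1
            positions.append(payload.index(acc))
        assert positions == sorted(positions)

    @pytest.mark.parametrize("source", sorted(BATCH3))
    def test_deterministic_payload(self, source):
        adapter = get_adapter(source)
        batch = BATCH3[source]
        assert adapter.build_request(batch).payload == adapter.build_request(batch).payload

    def test_string_url_is_parseable_rest_query(self):
        payload = get_adapter("STRING").build_request(BATCH3["STRING"]).payload
        parsed = urlparse("https://host/api/" + payload)
        query = parse_qs(parsed.query)
        assert query["species"] == ["9606"]
        assert "identifiers" in query

    def test_opentargets_payload_is_valid_graphql(self):
        payload = get_adapter("OpenTargets").build_request(BATCH3["OpenTargets"]).payload
        validate_graphql(payload)  # raises on syntax error

    def test_bgee_payload_is_valid_sparql(self):
        payload = get_adapter("Bgee").build_request(BATCH3["Bgee"]).payload
        prepareQuery(payload)  # raises on syntax error

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            get_adapter("Bgee").build_request([])

    def test_graphql_checker_rejects_malformed_documents(self):
        for bad in ("query {", "query { }", "{ field(: 1) }", "query @ {x}"):
            with pytest.raises(GraphQLSyntaxError):
                validate_graphql(bad)


class TestParseResponse:
    def test_disgenet_two_associations(self):
        body = json.dumps(
            {
                "status": "OK",
                "payload": [
                    {"gene_ncbi_id": 1001, "disease_umls": "C1", "disease_name": "d1",
                     "score": 0.5},
                    {"gene_ncbi_id": 1002, "disease_umls": "C2", "disease_name": "d2",
                     "score": 0.7},
                ],
            }
        )
        rows = get_adapter("DisGeNET").parse_response(
            RawResponse("DisGeNET", body, 200), BATCH3["DisGeNET"]
        )
        assert len(rows) == 2
        assert all(r.relation == "associated_with" for r in rows)
        assert all(r.object_type == "disease" for r in rows)
        assert rows[0].object_key == "UMLS:C1"
        assert rows[0].edge_attributes["score"] == 0.5

    @pytest.mark.parametrize("source,body", [
        ("DisGeNET", '{"status": "OK", "payload": []}'),
        ("STRING", "[]"),
        ("MINERVA", '{"models": []}'),
        ("OpenTargets", '{"data": {}}'),
        ("Bgee", '{"head": {"vars": []}, "results": {"bindings": []}}'),
    ])
    def test_valid_empty_body_yields_no_rows(self, source, body):
        rows = get_adapter(source).parse_response(
            RawResponse(source, body, 200), BATCH3[source]
        )
        assert rows == []

    @pytest.mark.parametrize("source", sorted(BATCH3))
    def test_truncated_body_is_schema_drift(self, source):
        full = load_fixture_response(source).body
        truncated = RawResponse(source, full[: len(full) // 2], 200)
        with pytest.raises(SchemaDriftError):
            get_adapter(source).parse_response(truncated, load_fixture_batch(source))

    @pytest.mark.parametrize("source", sorted(BATCH3))
    def test_subjects_never_outside_batch(self, source):
        """Parsing a full fixture response with a narrower batch must not
        emit assertions anchored at the excluded entities."""
        response = load_fixture_response(source)
        narrow = load_fixture_batch(source)[:1]
        rows = get_adapter(source).parse_response(response, narrow)
        allowed = {narrow[0][0]}
        assert all(r.anchor_key in allowed for r in rows)

    def test_opentargets_mechanism_to_relation(self):
        response = load_fixture_response("OpenTargets")
        batch = load_fixture_batch("OpenTargets")
        rows = get_adapter("OpenTargets").parse_response(response, batch)
        relations = {r.relation for r in rows}
        assert "associated_with" in relations and "part_of" in relations
        compound_rows = [r for r in rows if r.subject_type == "compound"]
        assert compound_rows, "fixture should contain drug assertions"
        assert {r.relation for r in compound_rows} <= {"activates", "inhibits", "treats"}

    def test_bgee_expression_attributes(self):
        rows = get_adapter("Bgee").parse_response(
            load_fixture_response("Bgee"), load_fixture_batch("Bgee")
        )
        for r in rows:
            assert r.relation == "expressed_by"
            assert r.object_type == "anatomical_entity"
            assert set(r.edge_attributes) == {
                "expression_level", "developmental_stage", "over_expressed"
            }


class TestSelfTest:
    @pytest.mark.parametrize("source", sorted(CONCRETE_SOURCES))
    def test_golden_fixtures_pass(self, source):
        report = adapter_selftest(source)
        assert report.passed, report.diffs

    def test_mutated_field_name_fails_and_names_field(self):
        body = load_fixture_response("DisGeNET").body.replace('"score"', '"scores"')
        report = adapter_selftest("DisGeNET", RawResponse("DisGeNET", body, 200))
        assert not report.passed
        assert any("score" in d for d in report.diffs)

    def test_mutated_value_reports_field_level_diff(self):
        body = load_fixture_response("MINERVA").body.replace(
            "synthetic interferon signalling map", "renamed map"
        )
        report = adapter_selftest("MINERVA", RawResponse("MINERVA", body, 200))
        assert not report.passed
        assert any("object_attributes" in d for d in report.diffs)

    def test_non_concrete_source_is_error(self):
        with pytest.raises(UnsupportedSourceError):
            adapter_selftest("Wikidata")
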