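"""GraphDB-style repository manager with an injectable transport.

The manager never opens network connections itself: the transport is a
callable ``(method, url, body) -> (status, body)``. Every request issued
is recorded on the handle, so offline tests can assert exact payloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

from ..errors import EmptyPayloadError, TransportError

Transport = Callable[[str, str, str], tuple[int, str]]


@dataclass
class RecordedRequest:
    method: str
    url: str
    body: str


@dataclass
class TriplestoreManager:
    """Create repositories, upload Turtle, and pass through SPARQL queries."""

    endpoint_url: str
    transport: Transport
    requests: list[RecordedRequest] = field(default_factory=list)

    def _send(self, method: str, url: str, body: str) -> str:
        self.requests.append(RecordedRequest(method, url, body))
        try:
            status, response_body = self.transport(method, url, body)
        except Exception as exc:
            raise TransportError(f"{self.endpoint_url}: transport failed: {exc}") from exc
        if status >= 400:
            raise TransportError(f"{self.endpoint_url}: status {status}: {response_body}")
        return response_body

    def create_repository(self, repository_id: str) -> str:
        config = json.dumps({"id": repository_id, "type": "graphdb"}, sort_keys=True)
        return self._send("POST", f"{self.endpoint_url}/rest/repositories", config)

    def upload(self, repository_id: str, turtle: str) -> str:
        if not turtle.strip():
            raise EmptyPayloadError(
                f"refusing to upload an empty document to repository {repository_id!r}"
            )
        return self._send(
            "POST", f"{self.endpoint_url}/repositories/{repository_id}/statements", turtle
        )

    def sparql_query(self, repository_id: str, query: str) -> str:
        return self._send(
            "POST", f"{self.endpoint_url}/repositories/{repository_id}", query
        )
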