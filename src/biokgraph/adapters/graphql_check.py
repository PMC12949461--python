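"""Minimal GraphQL document syntax checker.

Covers the executable-document subset the adapters emit: one or more
operation definitions with optional names, aliased fields, inline scalar
arguments, and nested selection sets. Used by tests and self-tests to
assert that generated payloads are grammatically valid GraphQL; it is a
syntax checker only and performs no schema validation.
"""

from __future__ import annotations

import re

_TOKEN = re.compile(
    r"""
    (?P<ws>[\s,]+)
  | (?P<string>"(?:\\.|[^"\\])*")
  | (?P<number>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<name>[_A-Za-z][_0-9A-Za-z]*)
  | (?P<punct>[{}()\[\]:!=@$])
  | (?P<spread>\.\.\.)
    """,
    re.VERBOSE,
)


class GraphQLSyntaxError(ValueError):
    """Raised when a document does not match the supported grammar."""


def _tokenize(document: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(document):
        m = _TOKEN.match(document, pos)
        if m is None:
            raise GraphQLSyntaxError(f"illegal character at offset {pos}: {document[pos]!r}")
        pos = m.end()
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group()))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self, kind: str | None = None, value: str | None = None) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise GraphQLSyntaxError("unexpected end of document")
        if (kind and tok[0] != kind) or (value and tok[1] != value):
            raise GraphQLSyntaxError(f"unexpected token {tok[1]!r} at position {self.i}")
        self.i += 1
        return tok

    def document(self) -> None:
        while self.peek() is not None:
            self.operation()

    def operation(self) -> None:
        tok = self.peek()
        if tok and tok[0] == "name" and tok[1] in ("query", "mutation", "subscription"):
            self.take("name")
            if self.peek() and self.peek()[0] == "name":
                self.take("name")  # operation name
        self.selection_set()

    def selection_set(self) -> None:
        self.take("punct", "{")
        saw_field = False
        while True:
            tok = self.peek()
            if tok is None:
                raise GraphQLSyntaxError("unterminated selection set")
            if tok == ("punct", "}"):
                if not saw_field:
                    raise GraphQLSyntaxError("empty selection set")
                self.take("punct", "}")
                return
            self.field()
            saw_field = True

    def field(self) -> None:
        self.take("name")
        tok = self.peek()
        if tok == ("punct", ":"):  # alias
            self.take("punct", ":")
            self.take("name")
            tok = self.peek()
        if tok == ("punct", "("):
            self.arguments()
            tok = self.peek()
        if tok == ("punct", "{"):
            self.selection_set()

    def arguments(self) -> None:
        self.take("punct", "(")
        saw_arg = False
        while self.peek() != ("punct", ")"):
            self.take("name")
            self.take("punct", ":")
            self.value()
            saw_arg = True
        if not saw_arg:
            raise GraphQLSyntaxError("empty argument list")
        self.take("punct", ")")

    def value(self) -> None:
        tok = self.peek()
        if tok is None:
            raise GraphQLSyntaxError("missing argument value")
        if tok[0] in ("string", "number", "name"):
            self.take(tok[0])
        elif tok == ("punct", "["):
            self.take("punct", "[")
            while self.peek() != ("punct", "]"):
                self.value()
            self.take("punct", "]")
        else:
            raise GraphQLSyntaxError(f"unsupported value token {tok[1]!r}")


def validate_graphql(document: str) -> None:
    """Raise :class:`GraphQLSyntaxError` if the document is not valid."""
    parser = _Parser(_tokenize(document))
    parser.document()
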