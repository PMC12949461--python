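"""Exception hierarchy shared by all modules."""

from __future__ import annotations


class BiokgraphError(Exception):
    """Base class for all package errors."""


class UnsupportedKindError(BiokgraphError):
    """Input kind is not one of gene_list / metabolite_list / dea_table."""


class SchemaError(BiokgraphError):
    """A required column is missing from a tabular input."""


class InputParseError(BiokgraphError):
    """A cell could not be parsed; message carries the row number."""


class ConfigurationError(BiokgraphError):
    """Invalid or incomplete configuration."""


class MergeConflictError(BiokgraphError):
    """Two inputs mapped to one canonical key with conflicting DEA stats."""


class MappingFormatError(BiokgraphError):
    """Malformed identifier-mapping file; message carries the line number."""


class CatalogLookupError(BiokgraphError):
    """A selected source name is not in the catalog."""


class UnsupportedSourceError(BiokgraphError):
    """A source without a concrete adapter was selected for querying."""


class SchemaDriftError(BiokgraphError):
    """A source response did not match the adapter's expected shape."""


class IntegrityError(BiokgraphError):
    """A graph operation referenced a missing node or violated an invariant."""


class NodeTypeConflictError(BiokgraphError):
    """One key was asserted with two different node types."""


class SerializationError(BiokgraphError):
    """An attribute value cannot be represented in an output format."""


class GraphFormatError(BiokgraphError):
    """An imported document is structurally invalid."""


class InfeasibleSamplingError(BiokgraphError):
    """Negative sampling requested more combinations than exist."""


class TransportError(BiokgraphError):
    """A transport callable failed or returned a non-success status."""


class EmptyPayloadError(BiokgraphError):
    """A triple-store upload was attempted with an empty document."""
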