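"""Exception hierarchy shared across the package."""


class SeqIndexError(Exception):
    """Base class for all seqindex errors."""


class MalformedInputError(SeqIndexError):
    """A bank file (or record) violates its format's structure."""


class TruncatedRecordError(MalformedInputError):
    """A flat-file record is missing its terminator (``//``)."""


class SchemaError(SeqIndexError):
    """Invalid field-schema declaration or schema violation."""


class UnknownContentTypeError(SeqIndexError):
    """Content type was never registered."""


class ContentTypeConflictError(SeqIndexError):
    """Re-registration of a content type with a different descriptor."""


class PluginError(SeqIndexError):
    """Format plugin registration or contract failure."""


class QuerySyntaxError(SeqIndexError):
    """Query string does not parse; carries the 0-based column."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


class QueryError(SeqIndexError):
    """Semantically invalid query (bad field, bad bound type)."""


class FieldNotSearchableError(QueryError):
    """Query references a field that is stored but not indexed."""


class UnknownDocumentError(SeqIndexError):
    """doc_id not present in the committed index."""


class PartialUpdateError(SeqIndexError):
    """Partial update impossible because a field is indexed but not stored."""


class UnknownKeyError(SeqIndexError):
    """Chunk-store key not present."""


class SubrangeError(SeqIndexError):
    """Invalid start/stop subrange against a stored datum."""


class ShardUnreachableError(SeqIndexError):
    """A shard could not be opened/contacted; names the shard."""


class IntegrityError(SeqIndexError):
    """Original bank file changed since indexing (fetch mismatch)."""


class StoreError(SeqIndexError):
    """Chunk-store backend I/O failure."""
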