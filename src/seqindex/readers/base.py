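"""Reader registry, plugin mechanism, and the ParsedRecord envelope."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, IO, Iterator, Optional

from ..errors import PluginError
from ..model import ContentTypeRegistry, Document, default_registry

log = logging.getLogger("seqindex.readers")


@dataclass
class ParsedRecord:
    """One parser emission: a Document plus an optional raw-data payload.

    The payload (nucleic/protein sequence, a GenBank translation, a whole
    PDB body) is destined for the chunk store under *payload_id*, which
    defaults to the document's id.
    """

    document: Document
    payload: Optional[bytes] = None
    payload_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.payload is not None:
            if not self.payload_id:
                self.payload_id = self.document.doc_id
            if not self.payload_id:
                raise ValueError("payload present but payload_id empty")


Reader = Callable[..., Iterator[ParsedRecord]]


@dataclass(frozen=True)
class FormatPlugin:
    """A user-supplied reader for a new bank format.

    The reader is a procedure ``(binary stream, path, **kw) -> iterator of
    ParsedRecord`` and must obey the same source-location fidelity contract
    as the built-ins: the byte slice named by each document's
    SourceLocation re-parses to an equal document.
    """

    format_name: str
    reader: Reader
    content_type: str


class ReaderRegistry:
    """Maps ``-t <format>`` names to reader procedures."""

    def __init__(self, content_types: ContentTypeRegistry | None = None):
        self.content_types = content_types or default_registry()
        self._builtins: dict[str, Reader] = {}
        self._plugins: dict[str, FormatPlugin] = {}

    def _register_builtin(self, name: str, reader: Reader) -> None:
        self._builtins[name] = reader

    def register_plugin(self, plugin: FormatPlugin) -> None:
        if plugin.format_name in self._builtins:
            raise PluginError(
                f"plugin name {plugin.format_name!r} collides with a built-in format"
            )
        if plugin.content_type not in self.content_types:
            raise PluginError(
                f"plugin {plugin.format_name!r} emits unregistered content type "
                f"{plugin.content_type!r}"
            )
        self._plugins[plugin.format_name] = plugin

    def get(self, name: str) -> Reader:
        if name in self._builtins:
            return self._builtins[name]
        if name in self._plugins:
            return self._plugins[name].reader
        raise KeyError(
            f"unknown format {name!r}; available: {', '.join(self.available())}"
        )

    def available(self) -> list[str]:
        return sorted(set(self._builtins) | set(self._plugins))


def default_reader_registry(
    content_types: ContentTypeRegistry | None = None,
) -> ReaderRegistry:
    from .fasta import parse_fasta
    from .gff3 import parse_gff3
    from .genbank import parse_genbank
    from .embl import parse_embl
    from .pdb import parse_pdb

    reg = ReaderRegistry(content_types)
    reg._register_builtin("fasta", parse_fasta)
    reg._register_builtin("gff3", parse_gff3)
    reg._register_builtin("genbank", parse_genbank)
    reg._register_builtin("embl", parse_embl)
    reg._register_builtin("pdb", parse_pdb)
    return reg
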