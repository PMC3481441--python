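"""Field recoding: declarative per-field rewrite rules applied at index time.

A rule names a source field and one of four operations:

- ``split(sep)``   — split each value on *sep* into the named output fields
                     (e.g. ``db_xref`` ``taxon:9606`` → ``db_xref_db`` =
                     ``taxon``, ``db_xref_id`` = ``9606``); the original
                     field is kept.
- ``rename(new)``  — rename the field, values untouched.
- ``map(regex, template)`` — regex substitution of each value into the
                     first output field (original kept).
- ``drop``         — remove the field.

Rules apply in declaration order; a rule naming an absent field is a no-op.
A split whose separator does not occur in a value lets that value pass
through unsplit (logged).  Rules files are YAML lists of
``{field, op, args: [...], outputs: [...]}``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import IO, Iterable, Union

import yaml

from ..model import Document, Value
from .base import log

OPERATIONS = ("split", "rename", "map", "drop")


@dataclass(frozen=True)
class RecoderRule:
    field: str
    operation: str  # split | rename | map | drop
    args: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise ValueError(f"unknown recoder operation {self.operation!r}")
        if self.operation == "split" and (not self.args or not self.outputs):
            raise ValueError("split requires a separator arg and output field names")
        if self.operation == "rename" and not self.outputs:
            raise ValueError("rename requires the new field name in outputs")
        if self.operation == "map" and (len(self.args) != 2 or not self.outputs):
            raise ValueError("map requires (regex, template) args and an output name")


def apply_recoders(document: Document, rules: Iterable[RecoderRule]) -> Document:
    """Return a new Document with all rules applied in order."""
    fields: dict[str, list[Value]] = {k: list(v) for k, v in document.fields.items()}
    for rule in rules:
        values = fields.get(rule.field)
        if values is None:
            continue
        if rule.operation == "drop":
            del fields[rule.field]
        elif rule.operation == "rename":
            fields[rule.outputs[0]] = fields.pop(rule.field)
        elif rule.operation == "split":
            sep = rule.args[0]
            parts_per_output: list[list[Value]] = [[] for _ in rule.outputs]
            for v in values:
                s = str(v)
                if sep not in s:
                    log.warning("recoder split(%r) on %r: separator absent in %r",
                                sep, rule.field, s)
                    continue
                parts = s.split(sep, len(rule.outputs) - 1)
                for bucket, part in zip(parts_per_output, parts):
                    bucket.append(part)
            for name, bucket in zip(rule.outputs, parts_per_output):
                if bucket:
                    fields.setdefault(name, []).extend(bucket)
        elif rule.operation == "map":
            pattern, template = rule.args
            out = [re.sub(pattern, template, str(v)) for v in values]
            fields.setdefault(rule.outputs[0], []).extend(out)
    return Document(doc_id=document.doc_id, content_type=document.content_type,
                    fields=fields, source=document.source)


def load_recoders(config: Union[str, IO[str]]) -> list[RecoderRule]:
    if hasattr(config, "read"):
        data = yaml.safe_load(config.read())
    else:
        with open(config, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    rules = []
    for entry in data or []:
        rules.append(RecoderRule(
            field=entry["field"],
            operation=entry["op"],
            args=tuple(str(a) for a in entry.get("args", [])),
            outputs=tuple(entry.get("outputs", [])),
        ))
    return rules
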