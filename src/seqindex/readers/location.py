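"""Feature-location parsing shared by the GenBank and EMBL readers.

Compound locations (``join``, ``order``), fuzzy bounds (``<``, ``>``) and
multi-segment spans are reduced to their outermost ``min..max`` span so the
region driver always sees a single 1-based inclusive interval; the
reduction is flagged with ``location_exact: "false"`` on the document.
``complement(...)`` sets the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ..errors import MalformedInputError

_INT = re.compile(r"\d+")


@dataclass(frozen=True)
class Span:
    start: int  # 1-based
    end: int    # inclusive
    strand: str  # '+' or '-'
    exact: bool  # False when a compound/fuzzy location was reduced


def parse_location(text: str) -> Span:
    s = text.strip()
    strand = "+"
    exact = True
    if s.startswith("complement(") and s.endswith(")"):
        strand = "-"
        s = s[len("complement("):-1]
    if any(tok in s for tok in ("join(", "order(", "complement(", "<", ">")):
        exact = False
    positions = [int(m) for m in _INT.findall(s)]
    if not positions:
        raise MalformedInputError(f"unparseable feature location: {text!r}")
    return Span(start=min(positions), end=max(positions), strand=strand, exact=exact)
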