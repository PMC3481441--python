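"""Text analysis: the default tokenizer and fuzzy term matching.

The tokenizer emulates a Lucene-style standard analyzer: lowercase, split
on any character that is not a letter or digit, but keep ``.``, ``_`` and
``-`` when they sit *inside* an alphanumeric run (so accession-like tokens
``nm_000546.6`` survive whole, while ``GO:0005634`` splits at the colon).
Keyword fields bypass tokenization entirely (whole value, lowercased).

Fuzzy queries use the restricted Damerau–Levenshtein distance (insertions,
deletions, substitutions, and transposition of adjacent characters each
count one edit).
"""

from __future__ import annotations

import re
from typing import Iterable

_TOKEN = re.compile(r"[0-9a-zÀ-ɏ]+(?:[._-][0-9a-zÀ-ɏ]+)*")


def tokenize(text: str) -> list[str]:
    """Split *text* into normalized index tokens."""
    return _TOKEN.findall(str(text).lower())


def damerau_levenshtein(a: str, b: str, cap: int | None = None) -> int:
    """Restricted Damerau–Levenshtein edit distance.

    With *cap* given, returns ``cap + 1`` as soon as the distance provably
    exceeds *cap* (cheap rejection for vocabulary scans).
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if cap is not None and abs(la - lb) > cap:
        return cap + 1
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return prev[lb]


def fuzzy_expand(term: str, vocabulary: Iterable[str], max_edits: int) -> list[str]:
    """Vocabulary terms within *max_edits* Damerau–Levenshtein edits of *term*."""
    if max_edits not in (1, 2):
        raise ValueError(f"max_edits must be 1 or 2, got {max_edits}")
    return sorted(
        v for v in vocabulary
        if damerau_levenshtein(term, v, cap=max_edits) <= max_edits
    )
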