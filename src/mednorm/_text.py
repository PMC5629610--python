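"""Shared text normalization primitives.

A single tokenizer is used by every stage (lexicon indexing, candidate
generation, ranking) so that a mention and a lexicon name always agree on
what counts as a word.  Tokens are lowercased, split on whitespace and
slash, and stripped of punctuation other than intra-token hyphens (hyphens
are meaningful to the hyphenation rewriting rule and to abbreviation
detection, so they are preserved here and handled explicitly there).
"""

from __future__ import annotations

import re

__all__ = ["tokenize", "normalize", "edit_distance"]

# keep word characters and hyphens; everything else becomes a separator
_STRIP_RE = re.compile(r"[^\w\s/-]+")
_SPLIT_RE = re.compile(r"[\s/]+")


def tokenize(text: str) -> list[str]:
    """Split ``text`` into lowercase tokens.

    Splits on whitespace and slash; strips punctuation except hyphens,
    which stay inside tokens (``"ADA-SCID"`` is one token).  Leading and
    trailing hyphens left over from stripping are removed.
    """
    cleaned = _STRIP_RE.sub(" ", text.lower())
    tokens = []
    for raw in _SPLIT_RE.split(cleaned):
        tok = raw.strip("-")
        if tok:
            tokens.append(tok)
    return tokens


def normalize(text: str) -> str:
    """Canonical string form: tokens joined by single spaces."""
    return " ".join(tokenize(text))


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance; used only for deterministic tie-breaking."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
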