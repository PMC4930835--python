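"""Shared text normalization.

Every component that compares text against the controlled vocabularies —
lexicon construction, the dictionary tagger and the retrieval index — must
tokenize identically, otherwise dictionary surfaces silently stop matching.
This module is the single definition of that normalization.

A token is a maximal run of letters, digits and ``+``; every other character
is a separator.  The ``+`` rule keeps chemistry-flavoured forms such as
``h+/k+ atpase`` distinct from ``h/k atpase`` while ``/`` and ``-`` still act
as token breaks.  Matching is exact token-sequence equality after
lowercasing: no stemming, no fuzzy matching.
"""

from __future__ import annotations

import re
from typing import NamedTuple

# \w covers unicode letters/digits plus underscore; underscores are mapped to
# spaces beforehand so they behave as separators like every other punctuation.
_TOKEN_RE = re.compile(r"[\w+]+")


class TokenSpan(NamedTuple):
    """A token with its character offsets in the original text (half-open)."""

    token: str
    start: int
    end: int


def tokenize_with_spans(text: str) -> list[TokenSpan]:
    """Tokenize ``text``, keeping character offsets into the original string."""
    lowered = text.lower().replace("_", " ")
    return [TokenSpan(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(lowered)]


def tokenize(text: str) -> list[str]:
    """Lowercased token sequence of ``text``."""
    return [t.token for t in tokenize_with_spans(text)]


def normalize_surface(surface: str) -> str:
    """Canonical single-string key for a vocabulary surface.

    Tokens joined by single spaces; the empty string if the surface contains
    no token characters at all.
    """
    return " ".join(tokenize(surface))
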