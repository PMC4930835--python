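"""Dictionary-based named-entity recognition over titles and abstracts.

The tagger is a greedy longest-descriptor matcher: scanning left to right,
at each token position the longest lexicon surface starting there is taken
and its tokens are consumed, so the most specific entity wins — "papillary
breast cancer" is reported as one mention rather than as "breast cancer" or
"cancer".  Matches never overlap within one vocabulary; different
vocabularies are applied independently, so cross-vocabulary overlaps are
allowed.

When two term identifiers share the same longest surface at a position, both
are reported (the ambiguity is preserved rather than silently resolved).

Mentions are aggregated into annotation tuples
``{pmid, term id, term frequency, textual form}``, where the textual form is
the lowercased original text span of the match — distinct synonym spellings
of one term (e.g. "gastric h/k atpase" vs "gastric h+/k+ atpase") therefore
yield distinct records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .corpus import Document
from .terminology import Lexicon
from .text import tokenize_with_spans


@dataclass(frozen=True)
class Mention:
    """One dictionary match in one field of one document.

    ``start``/``end`` are 0-based half-open token indices within the field;
    ``char_start``/``char_end`` are character offsets used to recover the
    textual form.
    """

    pmid: str
    term_id: str
    surface: str
    field: str
    start: int
    end: int
    char_start: int
    char_end: int


@dataclass(frozen=True)
class AnnotationRecord:
    """The stored annotation tuple {pmid, term id, tf, textual form}."""

    pmid: str
    term_id: str
    tf: int
    form: str

    def __post_init__(self) -> None:
        if self.tf < 1:
            raise ValueError(f"tf must be >= 1, got {self.tf} for {self.pmid}/{self.term_id}")


def annotate_text(
    text: str, lexicon: Lexicon, pmid: str = "", field: str = "abstract"
) -> list[Mention]:
    """Greedy longest-match scan of ``text`` against one lexicon.

    Returns mentions in left-to-right order; ties between term ids sharing
    the matched surface produce one mention per term id, in sorted id order.
    """
    spans = tokenize_with_spans(text)
    n = len(spans)
    max_len = lexicon.max_tokens
    mentions: list[Mention] = []
    i = 0
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            key = " ".join(s.token for s in spans[i : i + length])
            term_ids = lexicon.surface_map.get(key)
            if term_ids:
                for term_id in sorted(term_ids):
                    mentions.append(
                        Mention(
                            pmid=pmid,
                            term_id=term_id,
                            surface=key,
                            field=field,
                            start=i,
                            end=i + length,
                            char_start=spans[i].start,
                            char_end=spans[i + length - 1].end,
                        )
                    )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def mention_form(mention: Mention, text: str) -> str:
    """Lowercased original text span of a mention."""
    return text[mention.char_start : mention.char_end].lower()


def annotate_document(doc: Document, lexicons: Iterable[Lexicon]) -> list[AnnotationRecord]:
    """Annotate title and abstract against each lexicon independently.

    Mentions are pooled across title and abstract, aggregated by
    ``(term_id, form)`` with occurrence counts summed, and returned in
    canonical ``(term_id, form)`` order.
    """
    counts: dict[tuple[str, str], int] = {}
    for lexicon in lexicons:
        for field_name, text in (("title", doc.title), ("abstract", doc.abstract)):
            for mention in annotate_text(text, lexicon, pmid=doc.pmid, field=field_name):
                key = (mention.term_id, mention_form(mention, text))
                counts[key] = counts.get(key, 0) + 1
    return [
        AnnotationRecord(pmid=doc.pmid, term_id=term_id, tf=tf, form=form)
        for (term_id, form), tf in sorted(counts.items())
    ]
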