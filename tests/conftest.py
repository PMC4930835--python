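"""Shared fixtures: miniature vocabularies, corpora and oracle helpers."""

from __future__ import annotations

import pytest

from litriage.corpus import Corpus, Document
from litriage.terminology import (
    Lexicon,
    RefinementPolicy,
    SynonymRecord,
    TermEntry,
    Vocabulary,
    build_lexicon,
)

# A GO biological-process stanza with two EXACT synonyms, plus dangling
# is_a parents, in OBO 1.2 flat format.
GO_BP_STANZA = """\
format-version: 1.2
ontology: go-mini

[Term]
id: GO:0030318
name: melanocyte differentiation
namespace: biological_process
def: "The process in which a relatively unspecialized cell acquires specialized features of a melanocyte." [GOC:mah]
synonym: "melanocyte cell differentiation" EXACT []
synonym: "melanophore differentiation" EXACT []
is_a: GO:0050931 ! pigment cell differentiation
is_a: GO:0060563 ! neuroepithelial cell differentiation
"""


@pytest.fixture
def go_obo(tmp_path):
    path = tmp_path / "go-mini.obo"
    path.write_text(GO_BP_STANZA, encoding="utf-8")
    return path


@pytest.fixture
def permissive_policy():
    """No stopwords, minimum length 1: keeps every surface."""
    return RefinementPolicy(stopword_list=frozenset(), min_surface_length=1)


def make_lexicon(surface_to_terms: dict[str, str | set[str]], axis: str = "DISEASES") -> Lexicon:
    """Build a lexicon directly from {raw surface: term id(s)}."""
    vocab = Vocabulary(name="adhoc", axis=axis)
    grouped: dict[str, list[str]] = {}
    for surface, tids in surface_to_terms.items():
        ids = {tids} if isinstance(tids, str) else set(tids)
        for tid in ids:
            grouped.setdefault(tid, []).append(surface)
    for tid, surfaces in sorted(grouped.items()):
        vocab.add(
            TermEntry(
                term_id=tid,
                preferred_name=surfaces[0],
                synonyms=tuple(SynonymRecord(surface=s) for s in surfaces[1:]),
                axis=axis,
            )
        )
    return build_lexicon(vocab, RefinementPolicy(stopword_list=frozenset(), min_surface_length=1))


@pytest.fixture
def cancer_lexicon():
    """Nested disease surfaces exercising longest-descriptor preference."""
    return make_lexicon(
        {
            "papillary breast cancer": "C9134",
            "breast cancer": "C4872",
            "cancer": "C9305",
        }
    )


@pytest.fixture
def tiny_corpus():
    docs = [
        Document(pmid="101", title="alpha beta", abstract="gamma delta gamma", year=2001),
        Document(
            pmid="102",
            title="alpha review",
            abstract="gamma epsilon",
            year=1989,
            pub_types=frozenset({"Review"}),
        ),
        Document(pmid="103", title="zeta", abstract="", year=2010),
    ]
    corpus = Corpus()
    for doc in docs:
        corpus.add(doc)
    return corpus
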