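"""Inverted index and weighting models, against closed-form oracles."""

from __future__ import annotations

import math
import random
import re

import pytest

from litriage.corpus import Corpus, Document
from litriage.retrieval import (
    InvertedIndex,
    WeightingSchema,
    build_index,
    ingest_external_ranking,
    score_document,
    search,
    write_trec_run,
)
from litriage.text import tokenize


def reference_bm25(corpus: Corpus, query: list[str], pmid: str, k1=1.2, b=0.75) -> float:
    """Independent closed-form BM25 over raw document texts.

    Recomputes every statistic (tf, df, dl, avgdl, N) from scratch with its
    own tokenization, separately from the inverted index.
    """
    token_re = re.compile(r"[\w+]+")

    def toks(doc):
        return token_re.findall((doc.title + " " + doc.abstract).lower().replace("_", " "))

    docs = {d.pmid: toks(d) for d in corpus}
    n = len(docs)
    avgdl = sum(len(t) for t in docs.values()) / n
    dl = len(docs[pmid])
    score = 0.0
    for t in set(query):
        df = sum(1 for toks_ in docs.values() if t in toks_)
        if df == 0:
            continue
        tf = docs[pmid].count(t)
        if tf == 0:
            continue
        idf = math.log((n - df + 0.5) / (df + 0.5) + 1)
        for _ in range(query.count(t)):
            score += idf * tf * (k1 + 1) / (tf + k1 * (1 - b + b * dl / avgdl))
    return score


def make_corpus(texts: dict[str, str]) -> Corpus:
    corpus = Corpus()
    for pmid, text in texts.items():
        corpus.add(Document(pmid=pmid, title="", abstract=text))
    return corpus


@pytest.fixture
def three_doc_corpus():
    return make_corpus(
        {
            "1": "kinase binds the membrane kinase",
            "2": "membrane transport of ions",
            "3": "kinase kinase kinase signal",
        }
    )


class TestBuildIndex:
    def test_collection_statistics(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        assert index.n_docs == 3
        assert len(index.postings["membrane"]) == 2
        assert index.doc_lengths == {"1": 5, "2": 4, "3": 4}
        assert index.avgdl == pytest.approx(sum(index.doc_lengths.values()) / 3)

    def test_empty_abstract_indexed_from_title(self):
        corpus = Corpus()
        corpus.add(Document(pmid="1", title="solo title", abstract=""))
        index = build_index(corpus)
        assert index.doc_lengths["1"] == 2
        assert "solo" in index.postings

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            build_index(Corpus())

    def test_insertion_order_invariance(self, three_doc_corpus):
        shuffled = Corpus()
        for pmid in ["3", "1", "2"]:
            shuffled.add(three_doc_corpus[pmid])
        a = build_index(three_doc_corpus)
        b = build_index(shuffled)
        query = ["kinase", "membrane"]
        for pmid in ["1", "2", "3"]:
            assert score_document(a, query, pmid, WeightingSchema()) == pytest.approx(
                score_document(b, query, pmid, WeightingSchema())
            )


class TestBM25:
    def test_absent_query_scores_zero(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        assert score_document(index, ["unseen"], "1", WeightingSchema()) == 0.0

    def test_matches_closed_form_on_toy_corpus(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        schema = WeightingSchema(model="bm25", k1=1.2, b=0.75)
        for pmid in ["1", "2", "3"]:
            got = score_document(index, ["kinase"], pmid, schema)
            assert got == pytest.approx(reference_bm25(three_doc_corpus, ["kinase"], pmid), abs=1e-9)

    def test_matches_closed_form_on_random_small_corpora(self):
        """Equality with the independent oracle on every <=10-doc fixture."""
        rng = random.Random(42)
        vocabulary = ["alpha", "beta", "gamma", "delta", "kinase", "membrane", "ion"]
        for _ in range(50):
            n = rng.randint(2, 10)
            corpus = make_corpus(
                {
                    str(i): " ".join(rng.choice(vocabulary) for _ in range(rng.randint(3, 20)))
                    for i in range(n)
                }
            )
            index = build_index(corpus)
            query = [rng.choice(vocabulary) for _ in range(rng.randint(1, 3))]
            for pmid in corpus.documents:
                got = score_document(index, query, pmid, WeightingSchema())
                assert got == pytest.approx(reference_bm25(corpus, query, pmid), abs=1e-9)

    def test_monotone_in_term_frequency(self):
        # identical lengths; doc "b" has twice the query-term count of "a"
        corpus = make_corpus(
            {"a": "kinase pad pad pad", "b": "kinase kinase pad pad", "c": "other words here now"}
        )
        index = build_index(corpus)
        schema = WeightingSchema()
        assert score_document(index, ["kinase"], "b", schema) > score_document(
            index, ["kinase"], "a", schema
        )


class TestDFR:
    def test_nonnegative_and_zero_when_absent(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        schema = WeightingSchema(model="dfr")
        assert score_document(index, ["unseen"], "1", schema) == 0.0
        for pmid in ["1", "2", "3"]:
            assert score_document(index, ["kinase"], pmid, schema) >= 0.0

    def test_prefers_term_rich_document_at_equal_length(self):
        corpus = make_corpus(
            {"a": "kinase pad pad pad", "b": "kinase kinase kinase pad", "c": "noise toks here now"}
        )
        index = build_index(corpus)
        schema = WeightingSchema(model="dfr")
        assert score_document(index, ["kinase"], "b", schema) > score_document(
            index, ["kinase"], "a", schema
        )


class TestCombined:
    def test_lambda_one_matches_bm25_ranking(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        pure = search(index, ["kinase", "membrane"], WeightingSchema(model="bm25"), limit=3)
        mixed = search(
            index, ["kinase", "membrane"], WeightingSchema(model="combined", lambda_mix=1.0), limit=3
        )
        assert [d.pmid for d in pure] == [d.pmid for d in mixed]

    def test_scores_bounded_in_unit_interval(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        results = search(index, ["kinase"], WeightingSchema(model="combined"), limit=3)
        assert all(0.0 <= d.search_score <= 1.0 for d in results)


class TestSearch:
    def test_single_matching_doc_ranked_first(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        results = search(index, ["transport"], limit=5)
        assert results[0].pmid == "2"

    def test_higher_tf_outranks_at_equal_length(self):
        corpus = make_corpus(
            {
                "A": "query query query query query",
                "B": "query other other other other",
                "C": "none of these words match",
            }
        )
        index = build_index(corpus)
        results = search(index, ["query"], limit=5)
        assert [d.pmid for d in results[:2]] == ["A", "B"]

    def test_limit_larger_than_corpus_returns_all_matches(self, three_doc_corpus):
        index = build_index(three_doc_corpus)
        results = search(index, ["kinase"], limit=100)
        assert {d.pmid for d in results} == {"1", "3"}

    def test_empty_query_is_an_error(self, three_doc_corpus):
        with pytest.raises(ValueError):
            search(build_index(three_doc_corpus), [], limit=5)

    def test_equal_scores_break_ties_by_larger_pmid(self):
        corpus = make_corpus({"11": "same text here", "9": "same text here"})
        index = build_index(corpus)
        results = search(index, ["same"], limit=2)
        assert [d.pmid for d in results] == ["11", "9"]


class TestExternalRanking:
    def test_order_preserved_scores_zero(self):
        docs = ingest_external_ranking(["p1", "p2", "p3"])
        assert [d.pmid for d in docs] == ["p1", "p2", "p3"]
        assert all(d.search_score == 0.0 for d in docs)

    def test_single_pmid(self):
        docs = ingest_external_ranking(["only"])
        assert docs == [type(docs[0])(pmid="only", search_score=0.0)]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            ingest_external_ranking(["p1", "p1"])


def test_trec_run_format(tmp_path):
    path = write_trec_run(tmp_path / "run.txt", {"Q1": [("7", 2.5), ("3", 1.0)]}, tag="t")
    assert path.read_text(encoding="utf-8") == "Q1 Q0 7 1 2.500000 t\nQ1 Q0 3 2 1.000000 t\n"


def test_schema_validation():
    with pytest.raises(ValueError):
        WeightingSchema(k1=0)
    with pytest.raises(ValueError):
        WeightingSchema(b=1.5)
    with pytest.raises(ValueError):
        WeightingSchema(model="tfidf")


def test_index_save_load_round_trip(tmp_path, three_doc_corpus):
    index = build_index(three_doc_corpus)
    path = tmp_path / "index.json"
    index.save(path)
    loaded = InvertedIndex.load(path)
    assert loaded.doc_lengths == index.doc_lengths
    assert loaded.postings == index.postings
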