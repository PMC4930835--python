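"""Query-dependent document scoring.

An inverted index over title+abstract tokens supports three weighting
models:

* ``bm25`` — Okapi BM25,
  ``sum_t idf(t) * tf*(k1+1) / (tf + k1*(1 - b + b*dl/avgdl))`` with
  ``idf(t) = ln((N - df + 0.5)/(df + 0.5) + 1)`` (the non-negative variant).
* ``dfr`` — a divergence-from-randomness instance in the In_expB2 style:
  informative content from the inverse *expected* document frequency under a
  Bernoulli model, a Bernoulli after-effect (B2) gain, and length
  normalization 2 (``tfn = tf * log2(1 + c*avgdl/dl)``, default c = 1).
* ``combined`` — per-query min-max normalization of both scores over the
  candidate set, then a convex mix ``lambda_mix*bm25 + (1-lambda_mix)*dfr``.

A second, external research mode takes an externally ranked pmid list (e.g.
a PubMed Boolean result) as-is: every search score is 0 and the rank is the
given order, so downstream re-ranking reduces to the entity-density terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Corpus
from .text import tokenize


@dataclass
class InvertedIndex:
    """Token postings plus the collection statistics the models need."""

    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    doc_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)

    @property
    def avgdl(self) -> float:
        if not self.doc_lengths:
            return 0.0
        return sum(self.doc_lengths.values()) / len(self.doc_lengths)

    def save(self, path: str | Path) -> None:
        import json

        payload = {
            "doc_lengths": {p: self.doc_lengths[p] for p in sorted(self.doc_lengths)},
            "postings": {
                t: {p: self.postings[t][p] for p in sorted(self.postings[t])}
                for t in sorted(self.postings)
            },
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        import json

        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(postings=payload["postings"], doc_lengths=payload["doc_lengths"])


@dataclass(frozen=True)
class WeightingSchema:
    """Retrieval model choice and its parameters."""

    model: str = "bm25"
    k1: float = 1.2
    b: float = 0.75
    lambda_mix: float = 0.5
    dfr_c: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in {"bm25", "dfr", "combined"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must be in [0, 1]")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")


@dataclass(frozen=True)
class ScoredDoc:
    pmid: str
    search_score: float


def build_index(corpus: Corpus) -> InvertedIndex:
    """Index title+abstract of every document with the shared tokenizer."""
    if len(corpus) == 0:
        raise ValueError("cannot index an empty corpus")
    index = InvertedIndex()
    for pmid in sorted(corpus.documents):
        doc = corpus.documents[pmid]
        tokens = tokenize(doc.title) + tokenize(doc.abstract)
        index.doc_lengths[pmid] = len(tokens)
        for token in tokens:
            bucket = index.postings.setdefault(token, {})
            bucket[pmid] = bucket.get(pmid, 0) + 1
    return index


def _bm25(index: InvertedIndex, query_tokens: Sequence[str], pmid: str, k1: float, b: float) -> float:
    n = index.n_docs
    avgdl = index.avgdl
    dl = index.doc_lengths[pmid]
    score = 0.0
    for token in query_tokens:
        posting = index.postings.get(token)
        if not posting:
            continue
        tf = posting.get(pmid, 0)
        if tf == 0:
            continue
        df = len(posting)
        idf = math.log((n - df + 0.5) / (df + 0.5) + 1.0)
        score += idf * tf * (k1 + 1.0) / (tf + k1 * (1.0 - b + b * dl / avgdl))
    return score


def _dfr(index: InvertedIndex, query_tokens: Sequence[str], pmid: str, c: float) -> float:
    n = index.n_docs
    avgdl = index.avgdl
    dl = index.doc_lengths[pmid]
    score = 0.0
    for token in query_tokens:
        posting = index.postings.get(token)
        if not posting:
            continue
        tf = posting.get(pmid, 0)
        if tf == 0:
            continue
        df = len(posting)
        coll_tf = sum(posting.values())
        # Length normalization 2.
        tfn = tf * math.log2(1.0 + c * avgdl / dl)
        # Expected df under a Bernoulli occurrence model of the coll_tf tokens.
        n_exp = n * (1.0 - ((n - 1.0) / n) ** coll_tf) if n > 1 else 1.0
        info = tfn * math.log2((n + 1.0) / (n_exp + 0.5))
        gain = (coll_tf + 1.0) / (df * (tfn + 1.0))
        score += max(gain * info, 0.0)
    return score


def _minmax(values: dict[str, float]) -> dict[str, float]:
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {p: (1.0 if hi > 0 else 0.0) for p in values}
    return {p: (v - lo) / (hi - lo) for p, v in values.items()}


def _candidates(index: InvertedIndex, query_tokens: Sequence[str]) -> set[str]:
    pmids: set[str] = set()
    for token in query_tokens:
        pmids.update(index.postings.get(token, ()))
    return pmids


def score_document(
    index: InvertedIndex, query_tokens: Sequence[str], pmid: str, schema: WeightingSchema
) -> float:
    """Score one indexed document for a query; unknown pmids are an error.

    For the combined model the min-max normalization runs over the query's
    candidate set (documents containing at least one query token).
    """
    if pmid not in index.doc_lengths:
        raise KeyError(f"pmid {pmid} is not indexed")
    if schema.model == "bm25":
        return _bm25(index, query_tokens, pmid, schema.k1, schema.b)
    if schema.model == "dfr":
        return _dfr(index, query_tokens, pmid, schema.dfr_c)
    scores = _combined_scores(index, query_tokens, schema)
    return scores.get(pmid, 0.0)


def _combined_scores(
    index: InvertedIndex, query_tokens: Sequence[str], schema: WeightingSchema
) -> dict[str, float]:
    cands = _candidates(index, query_tokens)
    bm25 = _minmax({p: _bm25(index, query_tokens, p, schema.k1, schema.b) for p in cands})
    dfr = _minmax({p: _dfr(index, query_tokens, p, schema.dfr_c) for p in cands})
    lam = schema.lambda_mix
    return {p: lam * bm25[p] + (1.0 - lam) * dfr[p] for p in cands}


def pmid_sort_key(pmid: str):
    """Descending-recency tie-break key: larger (numeric) pmid first, then
    reverse lexicographic.  Use with ascending sort."""
    if pmid.isdigit():
        return (0, -int(pmid), pmid)
    return (1, 0, _invert_string(pmid))


def _invert_string(s: str) -> tuple:
    return tuple(-ord(ch) for ch in s)


def search(
    index: InvertedIndex,
    query_tokens: Sequence[str],
    schema: WeightingSchema | None = None,
    limit: int = 50,
) -> list[ScoredDoc]:
    """Top-``limit`` candidate documents by score, deterministically ordered."""
    if not query_tokens:
        raise ValueError("empty query")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    schema = schema or WeightingSchema()
    if schema.model == "combined":
        scores = _combined_scores(index, query_tokens, schema)
    else:
        scores = {
            pmid: score_document(index, query_tokens, pmid, schema)
            for pmid in _candidates(index, query_tokens)
        }
    ordered = sorted(scores, key=lambda p: (-scores[p], pmid_sort_key(p)))
    return [ScoredDoc(pmid=p, search_score=scores[p]) for p in ordered[:limit]]


def ingest_external_ranking(pmids: Sequence[str]) -> list[ScoredDoc]:
    """Wrap an externally ranked pmid list: scores 0, given order preserved."""
    if not pmids:
        raise ValueError("external ranking must be non-empty")
    if len(set(pmids)) != len(pmids):
        raise ValueError("duplicate pmid in external ranking")
    return [ScoredDoc(pmid=p, search_score=0.0) for p in pmids]


def write_trec_run(
    path: str | Path, run: dict[str, list[tuple[str, float]]], tag: str = "litriage"
) -> Path:
    """Export ranked lists in TREC run format: ``qid Q0 pmid rank score tag``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for qid in sorted(run):
            for rank, (pmid, score) in enumerate(run[qid], start=1):
                fh.write(f"{qid} Q0 {pmid} {rank} {score:.6f} {tag}\n")
    return path
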