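"""Seeded synthetic test collections: vocabularies, corpora, benchmarks.

Real triage runs against full MEDLINE and proprietary curation benchmarks;
neither can ship with the package.  This module generates miniature stand-ins
with *known* structure so every component can be tested end to end offline:

* vocabularies with pronounceable multi-token surfaces (plus a deliberately
  short surface and a stopword surface to exercise refinement), written in
  both OBO and tabular dialects;
* corpora whose abstracts embed a known multiset of lexicon surfaces amid
  filler tokens, with the planted ground truth returned alongside — planting
  is the oracle for the tagger;
* QREL benchmarks whose relevance is controlled: driven by the planted
  entity-density of an axis (``by_index_size``), by the search signal alone
  (``by_search_only``), or a probabilistic mix (``mixed``).

Construction guarantees that filler tokens (all starting with ``z``) are
disjoint from vocabulary surface tokens (never starting with ``z``), that
planted surface occurrences are separated by fillers so greedy matching
recovers exactly the planted counts, and that abstracts are padded to a
fixed token length so search scores depend only on the planted query-token
frequency.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .corpus import Corpus, Document, write_documents
from .evaluation import Qrel, write_qrel
from .terminology import (
    Lexicon,
    RefinementPolicy,
    SynonymRecord,
    TermEntry,
    Vocabulary,
    build_lexicon,
    default_stopwords,
)
from .ner import AnnotationRecord

logger = logging.getLogger(__name__)

_CONSONANTS = "bcdfglmnprstv"  # no 'z' (reserved for fillers), no 'q'
_VOWELS = "aeiou"

#: Fixed abstract length in tokens; equal lengths keep retrieval scores a
#: function of term frequency only.
_ABSTRACT_TOKENS = 40

RELEVANCE_MODELS = ("by_index_size", "by_search_only", "mixed")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic collection."""

    seed: int = 0
    axis: str = "DISEASES"
    n_terms: int = 20
    synonyms_per_term: int = 2
    n_docs: int = 50
    mentions_mean: float = 2.0
    relevance_model: str = "by_index_size"
    alpha: float = 0.5
    n_queries: int = 5
    relevance_threshold: int = 2
    review_fraction: float = 0.1
    pre1990_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_terms < 1 or self.n_docs < 1 or self.n_queries < 1:
            raise ValueError("n_terms, n_docs and n_queries must be >= 1")
        if self.relevance_model not in RELEVANCE_MODELS:
            raise ValueError(f"unknown relevance model {self.relevance_model!r}")


class DocInfo(NamedTuple):
    qid: str
    search_tf: int
    index_size: int
    total_tf: int


@dataclass
class GroundTruth:
    """What was planted where: the oracle for tagging and benchmarks."""

    mentions: list[tuple[str, str, int]] = field(default_factory=list)  # (pmid, term_id, count)
    doc_info: dict[str, DocInfo] = field(default_factory=dict)


def _syllable(rng: np.random.Generator) -> str:
    return _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]


def _word(rng: np.random.Generator, syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(syllables))


def _filler(rng: np.random.Generator) -> str:
    return "z" + _word(rng, int(rng.integers(1, 3)))


def _query_token(qid_index: int) -> str:
    return f"zzq{qid_index}x"


def _term_id(axis: str, i: int) -> str:
    if axis.startswith("GO_"):
        return f"GO:{7000000 + i:07d}"
    return f"C{90000 + i}"


def gen_vocabulary(spec: FixtureSpec, out_dir: str | Path | None = None):
    """Generate a vocabulary; optionally write OBO and tabular files.

    Each term has one preferred name and ``synonyms_per_term`` synonyms with
    scopes cycling EXACT/NARROW/RELATED.  The first term's first synonym is a
    deliberately short (sub-4-character) surface and the second term's first
    synonym is a stopword, so refinement has something to drop.

    Returns ``(vocabulary, obo_path, tsv_path)``; paths are None when
    ``out_dir`` is not given.
    """
    rng = np.random.default_rng([1, spec.seed])
    vocab = Vocabulary(name=f"fixture-{spec.axis.lower()}", axis=spec.axis)
    used: set[str] = set()
    scopes = ("EXACT", "NARROW", "RELATED")

    def fresh_surface(n_tokens: int, n_syllables: int = 2) -> str:
        while True:
            surface = " ".join(_word(rng, n_syllables) for _ in range(n_tokens))
            if surface not in used:
                used.add(surface)
                return surface

    for i in range(spec.n_terms):
        name = fresh_surface(int(rng.integers(1, 4)))
        synonyms = []
        for j in range(spec.synonyms_per_term):
            if i == 0 and j == 0:
                surface = _word(rng, 1) + _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
                surface = surface[:3]  # below the default minimum length
            elif i == 1 and j == 0:
                surface = "about"  # a stopword; dropped by the default policy
            else:
                surface = fresh_surface(int(rng.integers(1, 3)))
            synonyms.append(SynonymRecord(surface=surface, syn_type=scopes[j % len(scopes)]))
        vocab.add(
            TermEntry(
                term_id=_term_id(spec.axis, i),
                preferred_name=name,
                synonyms=tuple(synonyms),
                axis=spec.axis,
            )
        )

    obo_path = tsv_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        obo_path = out_dir / "vocabulary.obo"
        tsv_path = out_dir / "vocabulary.tsv"
        _write_obo(vocab, obo_path)
        _write_tabular(vocab, tsv_path)
    return vocab, obo_path, tsv_path


_OBO_NAMESPACES = {"GO_MF": "molecular_function", "GO_BP": "biological_process", "GO_CC": "cellular_component"}


def _write_obo(vocab: Vocabulary, path: Path) -> None:
    lines = ["format-version: 1.2", f"ontology: {vocab.name}", ""]
    for entry in sorted(vocab, key=lambda e: e.term_id):
        lines.append("[Term]")
        lines.append(f"id: {entry.term_id}")
        lines.append(f"name: {entry.preferred_name}")
        if entry.axis in _OBO_NAMESPACES:
            lines.append(f"namespace: {_OBO_NAMESPACES[entry.axis]}")
        for syn in entry.synonyms:
            scope = syn.syn_type if syn.syn_type in {"EXACT", "NARROW", "RELATED", "BROAD"} else "RELATED"
            lines.append(f'synonym: "{syn.surface}" {scope} []')
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def _write_tabular(vocab: Vocabulary, path: Path) -> None:
    lines = ["term_id\tpreferred_name\tsynonym\tsyn_type"]
    for entry in sorted(vocab, key=lambda e: e.term_id):
        if not entry.synonyms:
            lines.append(f"{entry.term_id}\t{entry.preferred_name}\t\t")
        for syn in entry.synonyms:
            lines.append(f"{entry.term_id}\t{entry.preferred_name}\t{syn.surface}\t{syn.syn_type}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_policy() -> RefinementPolicy:
    return RefinementPolicy(stopword_list=default_stopwords())


def gen_corpus(
    spec: FixtureSpec, lexicon: Lexicon, out_dir: str | Path | None = None
) -> tuple[Corpus, GroundTruth, Path | None]:
    """Generate a corpus with planted mentions and its ground truth.

    Each document is assigned round-robin to one of ``n_queries`` queries and
    carries that query's token 1..3 times (always once under
    ``by_index_size``, so search signal is constant there).  Planted entity
    mentions are drawn Poisson(``mentions_mean``) over the lexicon's terms.
    Review publication types and pre-1990 years are assigned only to
    low-signal documents, so the post-ranking filters never remove a
    relevant document.
    """
    if not lexicon.surface_map:
        raise ValueError("lexicon is empty; generate/build it first")
    rng = np.random.default_rng([2, spec.seed])

    term_surfaces: dict[str, list[str]] = {}
    for surface in sorted(lexicon.surface_map):
        for tid in sorted(lexicon.surface_map[surface]):
            term_surfaces.setdefault(tid, []).append(surface)
    term_ids = sorted(term_surfaces)

    surface_tokens = {tok for s in lexicon.surface_map for tok in s.split()}
    corpus = Corpus()
    truth = GroundTruth()

    for i in range(spec.n_docs):
        pmid = str(9000000 + i)
        q_index = i % spec.n_queries
        qid = f"Q{q_index}"
        qtok = _query_token(q_index)

        if spec.relevance_model == "by_index_size":
            search_tf = 1
        else:
            search_tf = int(rng.integers(1, 4))

        n_mentions = int(rng.poisson(spec.mentions_mean))
        counts: dict[str, int] = {}
        for _ in range(n_mentions):
            tid = term_ids[int(rng.integers(len(term_ids)))]
            counts[tid] = counts.get(tid, 0) + 1

        # Under the density-driven relevance model, make distinct-term count
        # and raw term frequency distinguishable signals: some irrelevant
        # documents repeat a single term many times (term-frequency spam),
        # so a tf-ordering ranks them above genuinely dense documents.
        if (
            spec.relevance_model == "by_index_size"
            and len(counts) < spec.relevance_threshold
            and rng.random() < 0.35
        ):
            spam_tid = term_ids[int(rng.integers(len(term_ids)))]
            counts = {spam_tid: int(rng.integers(6, 9))}

        items: list[list[str]] = [[qtok]] * search_tf + [
            term_surfaces[tid][int(rng.integers(len(term_surfaces[tid])))].split()
            for tid in sorted(counts)
            for _ in range(counts[tid])
        ]
        # ensure the flattened items (well under the pad target) fit
        order = rng.permutation(len(items))
        tokens: list[str] = []
        for idx in order:
            tokens.extend(items[int(idx)])
            tokens.append(_filler(rng))  # separator: no accidental longer match
        while len(tokens) < _ABSTRACT_TOKENS:
            tokens.append(_filler(rng))
        abstract = " ".join(tokens)
        title = " ".join(_filler(rng) for _ in range(3))

        index_size = len(counts)
        total_tf = sum(counts.values())
        low_signal = index_size < spec.relevance_threshold and search_tf < 2
        pub_types: frozenset[str] = frozenset()
        year = 1995 + int(rng.integers(0, 19))
        if low_signal and rng.random() < spec.review_fraction:
            pub_types = frozenset({"Review"})
        if low_signal and rng.random() < spec.pre1990_fraction:
            year = 1985 + int(rng.integers(0, 5))

        corpus.add(Document(pmid=pmid, title=title, abstract=abstract, year=year, pub_types=pub_types))
        truth.doc_info[pmid] = DocInfo(qid=qid, search_tf=search_tf, index_size=index_size, total_tf=total_tf)
        for tid in sorted(counts):
            truth.mentions.append((pmid, tid, counts[tid]))

    fillers_used = {t for doc in corpus for t in doc.abstract.split() if t.startswith("z")}
    if fillers_used & surface_tokens:
        raise AssertionError("filler tokens collided with lexicon surfaces")

    path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = write_documents(corpus, out_dir / "corpus.jsonl")
        with (out_dir / "ground_truth.tsv").open("w", encoding="utf-8") as fh:
            fh.write("pmid\tterm_id\tcount\n")
            for pmid, tid, count in truth.mentions:
                fh.write(f"{pmid}\t{tid}\t{count}\n")
    return corpus, truth, path


def gen_benchmark(
    spec: FixtureSpec, corpus: Corpus, truth: GroundTruth
) -> tuple[list[tuple[str, str]], Qrel]:
    """Derive (queries, qrel) from the planted ground truth.

    ``by_index_size``: a document is relevant to its query iff its planted
    distinct-term count reaches ``relevance_threshold``.  ``by_search_only``:
    relevant iff the planted query-token frequency is at least 2.  ``mixed``:
    relevant with probability ``alpha``-weighted between the two signals.
    """
    rng = np.random.default_rng([3, spec.seed])
    queries = [(f"Q{k}", _query_token(k)) for k in range(spec.n_queries)]
    qrel: Qrel = {qid: set() for qid, _ in queries}
    for pmid in sorted(truth.doc_info):
        info = truth.doc_info[pmid]
        if spec.relevance_model == "by_index_size":
            relevant = info.index_size >= spec.relevance_threshold
        elif spec.relevance_model == "by_search_only":
            relevant = info.search_tf >= 2
        else:
            p = spec.alpha * (info.search_tf - 1) / 2.0 + (1 - spec.alpha) * min(
                info.index_size / max(spec.relevance_threshold, 1), 1.0
            )
            relevant = bool(rng.random() < min(max(p, 0.0), 1.0))
        if relevant:
            qrel[info.qid].add(pmid)
    for qid, _ in queries:
        if not qrel[qid]:
            logger.warning("benchmark query %s has no relevant documents", qid)
    return queries, qrel


def gen_fixture_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a complete collection; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vocab, obo_path, tsv_path = gen_vocabulary(spec, out_dir)
    lexicon = build_lexicon(vocab, default_policy())
    corpus, truth, corpus_path = gen_corpus(spec, lexicon, out_dir)
    queries, qrel = gen_benchmark(spec, corpus, truth)
    queries_path = out_dir / "queries.tsv"
    with queries_path.open("w", encoding="utf-8") as fh:
        fh.write("qid\tquery_text\n")
        for qid, text in queries:
            fh.write(f"{qid}\t{text}\n")
    qrel_path = write_qrel(out_dir / "benchmark.qrel", qrel)
    return {
        "obo": obo_path,
        "tsv": tsv_path,
        "corpus": corpus_path,
        "ground_truth": out_dir / "ground_truth.tsv",
        "queries": queries_path,
        "qrel": qrel_path,
    }


def worked_example_records() -> tuple[list[AnnotationRecord], dict[str, str]]:
    """The canonical annotation payload example and its term->axis map.

    A dehydration study of the gastric H+/K+ ATPase: one disease concept,
    two synonym spellings of the hydrogen:potassium-exchanging ATPase
    activity term, and three occurrences of "membrane" — six concept
    occurrences in four records for pmid 23883606.
    """
    pmid = "23883606"
    records = [
        AnnotationRecord(pmid=pmid, term_id="C26740", tf=1, form="dehydration"),
        AnnotationRecord(pmid=pmid, term_id="GO:0008900", tf=1, form="gastric h/k atpase"),
        AnnotationRecord(pmid=pmid, term_id="GO:0008900", tf=1, form="gastric h+/k+ atpase"),
        AnnotationRecord(pmid=pmid, term_id="GO:0016020", tf=3, form="membrane"),
    ]
    axis_map = {"C26740": "DISEASES", "GO:0008900": "GO_MF", "GO:0016020": "GO_CC"}
    return records, axis_map
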