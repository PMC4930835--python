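"""Axis-specific re-ranking of retrieved documents.

The triage score of an article for a curation axis is a linear combination
of three factors: the search-engine score, the number of distinct matched
terms of that axis (the matching index size) and the summed term frequency:

    article_score = a * search_score + b * matching_index_size + c * total_tf

The shipped presets are the tuned axis formulas:

* Diseases:            1.0 * search + 0.5 * index size
* Biological process:  0.9 * search + 1.0 * index size
* Molecular function:  1.5 * search + 0.3 * term frequency

Before scoring, retrieved documents pass a post-ranking filter that drops
retracted articles and reviews (publication types unfit for curation) and,
optionally, documents published before a lower year bound (inclusive).
Queries may be expanded with user-supplied gene synonyms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import Corpus, Document
from .retrieval import (
    InvertedIndex,
    ScoredDoc,
    WeightingSchema,
    ingest_external_ranking,
    pmid_sort_key,
    search,
)
from .store import AnnotationStore, axis_profile
from .text import tokenize

#: Publication types excluded from curation by default.
DEFAULT_EXCLUDED_PUB_TYPES = frozenset({"Review", "Retracted Publication"})

#: Axes for which a tuned preset exists.
RANKED_AXES = ("DISEASES", "GO_BP", "GO_MF")


@dataclass(frozen=True)
class AxisWeights:
    """Coefficients of the linear ranking function."""

    a_search: float
    b_index: float
    c_tf: float

    def __post_init__(self) -> None:
        if self.a_search == self.b_index == self.c_tf == 0:
            raise ValueError("at least one ranking coefficient must be non-zero")


#: Tuned per-axis presets, exactly as published.
AXIS_PRESETS: dict[str, AxisWeights] = {
    "DISEASES": AxisWeights(a_search=1.0, b_index=0.5, c_tf=0.0),
    "GO_BP": AxisWeights(a_search=0.9, b_index=1.0, c_tf=0.0),
    "GO_MF": AxisWeights(a_search=1.5, b_index=0.0, c_tf=0.3),
}


@dataclass(frozen=True)
class RankedArticle:
    """A pmid with its composite score and the three score components."""

    pmid: str
    composite_score: float
    components: tuple[float, int, int]  # (search_score, matching_index_size, total_tf)


@dataclass(frozen=True)
class TriageQuery:
    """The triage triplet {query — research mode — axis} plus filters.

    ``synonyms`` are expansion strings (e.g. gene synonyms looked up from a
    user-supplied table); ``external_pmids`` carries the externally ranked
    list consumed in ``external`` mode.
    """

    query_text: str
    axis: str
    mode: str = "vectorial"
    min_year: int | None = None
    synonyms: tuple[str, ...] = ()
    external_pmids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.axis not in RANKED_AXES:
            raise ValueError(f"unknown ranking axis {self.axis!r}; expected one of {RANKED_AXES}")
        if self.mode not in {"vectorial", "external"}:
            raise ValueError(f"unknown research mode {self.mode!r}")


def composite_score(components: Sequence[float], weights: AxisWeights) -> float:
    """Exact linear form a*search + b*index_size + c*tf."""
    s, m, t = components
    return weights.a_search * s + weights.b_index * m + weights.c_tf * t


def apply_filters(
    docs: Iterable[Document],
    min_year: int | None = None,
    excluded_pub_types: frozenset[str] = DEFAULT_EXCLUDED_PUB_TYPES,
) -> list[Document]:
    """Drop excluded publication types and too-old documents; keep order.

    The year bound is inclusive: ``min_year=1990`` keeps a 1990 paper.
    Documents with no year survive a year filter (their date is unknown).
    """
    kept = []
    for doc in docs:
        if excluded_pub_types and doc.pub_types & excluded_pub_types:
            continue
        if min_year is not None and doc.year is not None and doc.year < min_year:
            continue
        kept.append(doc)
    return kept


def expand_query(query_text: str, synonym_table: Mapping[str, Sequence[str]] | None = None) -> list[str]:
    """Tokens of the query plus those of its synonyms, deduplicated in order.

    A query absent from the table expands to its own tokens only.
    """
    tokens = list(tokenize(query_text))
    if synonym_table:
        for key in (query_text, query_text.lower(), query_text.upper()):
            if key in synonym_table:
                for syn in synonym_table[key]:
                    tokens.extend(tokenize(syn))
                break
    seen: set[str] = set()
    out: list[str] = []
    for tok in tokens:
        if tok not in seen:
            seen.add(tok)
            out.append(tok)
    return out


def load_synonym_table(path) -> dict[str, list[str]]:
    """Read a user-supplied synonym TSV: ``name<TAB>synonym`` per line."""
    table: dict[str, list[str]] = {}
    from pathlib import Path

    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>synonym'")
        table.setdefault(parts[0].strip(), []).append(parts[1].strip())
    return table


def collect_candidates(
    query: TriageQuery,
    corpus: Corpus,
    index: InvertedIndex | None,
    store: AnnotationStore,
    schema: WeightingSchema | None = None,
    candidate_pool: int = 1000,
    excluded_pub_types: frozenset[str] = DEFAULT_EXCLUDED_PUB_TYPES,
    normalize_search: bool = False,
) -> list[RankedArticle]:
    """Retrieve, filter and profile candidates; composite score left at 0.

    This is the weight-independent half of :func:`rank_axis`; the tuner calls
    it once per query and then re-scores the same candidates for every grid
    point.
    """
    if query.mode == "external":
        scored = ingest_external_ranking(list(query.external_pmids))
    else:
        tokens = expand_query(query.query_text)
        for syn in query.synonyms:
            for tok in tokenize(syn):
                if tok not in tokens:
                    tokens.append(tok)
        if index is None:
            raise ValueError("vectorial mode requires an index")
        scored = search(index, tokens, schema, limit=candidate_pool)

    by_pmid = {sd.pmid: sd for sd in scored}
    docs = [corpus[sd.pmid] for sd in scored if sd.pmid in corpus]
    survivors = apply_filters(docs, min_year=query.min_year, excluded_pub_types=excluded_pub_types)

    scores = {d.pmid: by_pmid[d.pmid].search_score for d in survivors}
    if normalize_search and scores:
        lo, hi = min(scores.values()), max(scores.values())
        if hi > lo:
            scores = {p: (v - lo) / (hi - lo) for p, v in scores.items()}

    out = []
    for doc in survivors:
        profile = axis_profile(store, doc.pmid, query.axis)
        out.append(
            RankedArticle(
                pmid=doc.pmid,
                composite_score=0.0,
                components=(scores[doc.pmid], profile.matching_index_size, profile.total_tf),
            )
        )
    return out


def score_candidates(candidates: Sequence[RankedArticle], weights: AxisWeights, limit: int) -> list[RankedArticle]:
    """Apply the linear function, sort descending, break ties by recency."""
    rescored = [
        RankedArticle(
            pmid=c.pmid,
            composite_score=composite_score(c.components, weights),
            components=c.components,
        )
        for c in candidates
    ]
    rescored.sort(key=lambda r: (-r.composite_score, pmid_sort_key(r.pmid)))
    return rescored[:limit]


def rank_axis(
    query: TriageQuery,
    corpus: Corpus,
    index: InvertedIndex | None,
    store: AnnotationStore,
    weights: AxisWeights | None = None,
    limit: int = 50,
    schema: WeightingSchema | None = None,
    candidate_pool: int = 1000,
    excluded_pub_types: frozenset[str] = DEFAULT_EXCLUDED_PUB_TYPES,
    normalize_search: bool = False,
) -> list[RankedArticle]:
    """Full axis-driven triage: retrieve, filter, profile, score, rank.

    ``weights`` defaults to the tuned preset of the query's axis.  Only the
    top ``candidate_pool`` retrieval results are ever re-ranked.
    """
    if weights is None:
        weights = AXIS_PRESETS[query.axis]
    candidates = collect_candidates(
        query,
        corpus,
        index,
        store,
        schema=schema,
        candidate_pool=candidate_pool,
        excluded_pub_types=excluded_pub_types,
        normalize_search=normalize_search,
    )
    return score_candidates(candidates, weights, limit)


def ranked_to_run(ranked: Sequence[RankedArticle]) -> list[tuple[str, float]]:
    """(pmid, score) pairs for TREC run export."""
    return [(r.pmid, r.composite_score) for r in ranked]
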