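# Methods

This note records the models implemented in `litriage`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic test collections do and do not establish.

## Terminology refinement

A vocabulary surface (preferred name or synonym) becomes matchable only if
it survives the `RefinementPolicy`:

* `min_surface_length` (characters of the **raw** surface, before
  normalization; default 4).  Short surfaces are overwhelmingly acronyms
  that collide with ordinary English ("CAN", "ALS", "AIM").  Counting raw
  characters rather than normalized tokens keeps the rule simple and
  auditable.
* `stopword_list` — case-insensitive equality against a word list.  The
  packaged default is a list of ~450 frequent general-English words
  (`litriage/data/stopwords.txt`); it is deliberately a plain-text file so a
  deployment can swap in any other list.
* `included_syn_types` — EXACT, NARROW and RELATED synonym scopes are
  included by default, plus the PREFERRED/ABBREVIATION rows of tabular
  exports; BROAD synonyms are excluded because a broader surface, by
  definition, tags documents about something more general than the term.
  Experience with GO synonyms is that the EXACT/NARROW/RELATED choice moves
  results very little; the switch exists for exactly that experiment.

Both filters apply to every vocabulary, not only to the disease thesaurus;
a per-vocabulary policy object makes the narrower behaviour available where
wanted.

OBO parsing is delegated to `obonet`; the GO axis of a term is derived from
its `namespace` line, obsolete terms are skipped, and dangling `is_a`
targets are ignored.  Tabular vocabularies
(`term_id<TAB>preferred_name<TAB>synonym<TAB>syn_type`) cover thesauri that
arrive pre-flattened, e.g. a disease vocabulary already cross-enriched with
MeSH/UMLS synonyms — no live terminology service is consulted.

## Text normalization and matching

One tokenizer (`litriage.text`) is shared by lexicon construction, the
tagger and the retrieval index: lowercase; a token is a maximal run of
letters, digits and `+`; everything else separates.  The `+` rule preserves
the distinction between ion-pump spellings such as `h+/k+ atpase` and
`h/k atpase` while `/` and `-` still break tokens.  Matching is exact
token-sequence equality — no stemming, no fuzzy matching, no sentence
segmentation — because dictionary lookup is the method; anything softer
would change the precision characteristics the re-ranker depends on.

The tagger is greedy left-to-right longest-match: at each token position the
longest lexicon surface starting there is consumed.  Matches therefore never
overlap within one vocabulary; different vocabularies are tagged
independently and may overlap.  Two deliberate tie rules: when two term ids
share the same longest surface, **both** are reported (dropping either would
silently bias term frequencies); and the *textual form* stored with each
annotation tuple is the lowercased original character span, so distinct
synonym spellings of one term remain distinct records.

## Retrieval models

* **BM25** with the canonical Okapi defaults `k1 = 1.2`, `b = 0.75`, and the
  non-negative idf variant `ln((N − df + 0.5)/(df + 0.5) + 1)`.
* **DFR**, In_expB2 style: term frequency normalized for document length as
  `tfn = tf · log2(1 + c·avgdl/dl)` with `c = 1`; informative content
  `tfn · log2((N+1)/(n_e + 0.5))` where `n_e = N·(1 − ((N−1)/N)^F)` is the
  expected document frequency of a term with collection frequency `F` under
  a Bernoulli occurrence model; Bernoulli after-effect gain
  `(F+1)/(df·(tfn+1))`.  Contributions are clamped at zero.  The DFR family
  has many members; this closed-form instance was chosen for being standard,
  parameter-light and easy to verify, and `c` is configurable.
* **Combined**: per-query min-max normalization of both scores over the
  candidate set (documents containing at least one query token), then
  `λ·bm25 + (1−λ)·dfr` with `λ = 0.5` by default.  Min-max before mixing
  makes the combination scale-free; with `λ = 1` the ranking order reduces
  to BM25's.

Ties at equal score are broken by larger (numeric) pmid first — a recency
proxy mirroring the reverse-chronological bias of bibliographic search —
then reverse-lexicographically; every ordering in the package is therefore
deterministic.

The external research mode wraps an externally ranked PMID list with all
search scores set to 0, so the composite score degenerates to
`b·index_size + c·tf` and the external order is only overridden by entity
density.

## Ranking function

`article_score = a·search_score + b·matching_index_size + c·total_tf`, where
both density factors come from the annotation store restricted to the
queried axis: the matching index size counts *distinct* axis terms in the
document, `total_tf` sums their term frequencies.  Presets pin the tuned
axis formulas (Diseases `1.0/0.5/0`, BP `0.9/1.0/0`, MF `1.5/0/0.3`).

Raw engine scores are used by default; an optional per-query min-max
normalization flag exists because linear coefficients are only transferable
across engines on a fixed scale.  Only the top `candidate_pool = 1000`
retrieval results are re-ranked — triage re-orders a retrieved list, it does
not scan the corpus.  The post-ranking filter drops publication types
`{"Review", "Retracted Publication"}` (configurable) and documents older
than an inclusive `min_year`; documents with no year survive a year filter.
Filters never reorder survivors.

## Evaluation

Binary-relevance TREC conventions: P@k divides by `k` regardless of how many
documents were returned; AP uses the total number of relevant documents in
the qrel as denominator; reciprocal rank is 0 when nothing relevant is
retrieved; interpolated P0 is the maximum precision over all cutoffs at
which recall is attained.  Top-rank precision circulates under three names
(rank-1 precision, interpolated precision at recall 0, MRR), so all three
are computed and labelled distinctly; P@1 is the headline.  Relative gains
between two metric values are reported as `100·(new − base)/base`, rounded
half-to-even to one decimal; the gain is undefined for a zero baseline.

## Tuning

Exhaustive grid search over `(a, b, c)`; default grid `a ∈ {0, 0.1, …, 1.5}`,
`b ∈ {0, 0.1, …, 1.0}`, `c ∈ {0, 0.1, …, 0.5}` with the all-zero triple
removed (1055 combinations), spanning all preset values.  The default
objective is mean P@1.  Ties keep the earlier grid point, making results
re-runnable; note this means the *smallest* coefficients attaining the
optimum are returned — ranking metrics are invariant to scaling the weight
vector, so boundary values are only returned when quality is genuinely
monotone in a coefficient.  By default tuning evaluates on the same
benchmark it optimizes (the report says so); a held-out protocol is the
caller's responsibility.  The weight-independent work (retrieve, filter,
profile) is done once per query and each grid point only re-scores, so the
full grid costs milliseconds at benchmark scale.

## Synthetic collections

The generator emulates the *structure* of the real task, not its content:

* Vocabulary surfaces are pronounceable consonant-vowel strings of 1–3
  tokens; one deliberately short surface and one stopword surface are
  planted per vocabulary so the refinement filters are exercised.
* Abstracts are bags of filler tokens (all starting with `z`, provably
  disjoint from surface tokens) into which a known multiset of lexicon
  surfaces is planted, each occurrence separated by a filler so greedy
  matching recovers exactly the planted counts — the plant is the oracle.
* Each document carries the token of its assigned query; abstracts are
  padded to a fixed 40 tokens so all candidates of a query have equal
  length and the search score depends only on the planted query-token
  frequency.
* Relevance models: `by_index_size` (relevant iff the planted distinct-term
  count reaches a threshold, default 2; query-token frequency held at 1 so
  search carries no relevance signal), `by_search_only` (relevant iff the
  query token was planted at least twice), and `mixed(α)` (Bernoulli with a
  convex mix of both signals).  Under `by_index_size`, about a third of the
  low-density documents are given a single term repeated 6–8 times; this
  "tf spam" decorrelates distinct-term density from raw term frequency, so
  recovering `b > 0` rather than `c > 0` is an identifiable outcome, not an
  artifact.
* Review publication types and pre-1990 years are assigned only to
  low-signal documents, so filter behaviour is exercised without making the
  benchmark's optimum depend on filter luck.
* Defaults (50 documents, 20 terms, 5 queries, Poisson mean 2 mentions per
  document; 200 documents / 25 terms / 20 queries for the tuning benchmark)
  keep every workflow fast while leaving enough per-query candidates (~10)
  for ranking differences to be visible.

What passing on these fixtures shows: the matcher, scorer, filter, metric
and tuner implement their definitions exactly, end to end.  What it does not
show: performance on real abstracts — real text has ambiguous surfaces,
morphological variation, entity mentions correlated with topicality, and
relevance judgements far noisier than a planted threshold.  Absolute metric
values on fixtures say nothing about absolute curation precision.

## Numerical and degenerate-input choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); set iteration never reaches an output —
  every file the package writes is byte-reproducible under a fixed seed.
* Empty text, empty vocabularies and unknown pmids in the store are
  well-defined non-errors (empty mentions, empty lexicon with a warning, an
  error-payload).  An empty corpus cannot be indexed; an empty query cannot
  be searched; a zero-query benchmark cannot be tuned.
* Min-max over a constant candidate set maps every document to 1 when the
  constant is positive, else 0.
* The store replaces on re-insert of the same `(pmid, termid, form)` key;
  the JSON payload is serialized canonically (fixed key order, sorted
  records) so re-serialization is byte-identical.

## Known limitations

* No live MEDLINE/PubMed access, no weekly synchronization, no web UI, no
  UniProt synonym service (a user-supplied TSV stands in), no full-text
  processing, and no protein–protein interaction axis.
* Dictionary matching only: no abbreviation expansion, no disambiguation
  beyond reporting ambiguous term ids, no normalization of gene/protein
  mentions.
* The published coefficient presets were tuned on a particular engine's
  score scale; on any other index they are a starting point for the tuner,
  not a guarantee.
* Statistical comparison of runs (significance testing) is out of scope.
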