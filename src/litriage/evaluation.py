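"""TREC-style evaluation of ranked lists against relevance judgements.

Given a run (query -> ordered pmids) and a qrel (query -> relevant pmids,
binary relevance), compute per-query and mean:

* P@1 and P@10 — precision among the top 1 / top 10 returned documents;
* AP / MAP — average precision, with the standard trec_eval denominator
  (the total number of relevant documents in the qrel);
* RR / MRR — reciprocal rank of the first relevant document (0 if none);
* interpolated P0 — the interpolated precision at recall 0, i.e. the
  maximum precision over all cutoffs at which a relevant document appears.

P@1, interpolated P0 and MRR are all computed because top-rank precision is
reported under all three guises in the triage literature; they are labelled
distinctly and P@1 is the headline number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

Qrel = dict[str, set[str]]
Run = dict[str, list[str]]

METRIC_NAMES = ("p_at_1", "p_at_10", "ap", "rr", "interp_p0")


@dataclass(frozen=True)
class QueryMetrics:
    p_at_1: float
    p_at_10: float
    ap: float
    rr: float
    interp_p0: float


@dataclass
class MetricsReport:
    """Per-query metrics plus their means over evaluated queries."""

    per_query: dict[str, QueryMetrics]

    def mean(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {name!r}; expected one of {METRIC_NAMES}")
        if not self.per_query:
            return 0.0
        return sum(getattr(m, name) for m in self.per_query.values()) / len(self.per_query)

    @property
    def mean_p_at_1(self) -> float:
        return self.mean("p_at_1")

    @property
    def mean_p_at_10(self) -> float:
        return self.mean("p_at_10")

    @property
    def map(self) -> float:
        return self.mean("ap")

    @property
    def mrr(self) -> float:
        return self.mean("rr")

    @property
    def mean_interp_p0(self) -> float:
        return self.mean("interp_p0")


def load_qrel(path: str | Path) -> Qrel:
    """Read TREC qrel lines ``qid 0 docid rel``; rel > 0 means relevant.

    Duplicate (qid, docid) pairs: the last line wins, with a warning.
    Malformed lines raise ``ValueError`` with the line number.
    """
    judgements: dict[str, dict[str, int]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'qid 0 docid rel', got {line!r}")
        qid, _, docid, rel_text = parts
        try:
            rel = int(rel_text)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer relevance {rel_text!r}") from exc
        if docid in judgements.get(qid, {}):
            logger.warning("%s:%d: duplicate judgement for (%s, %s); last wins", path, lineno, qid, docid)
        judgements.setdefault(qid, {})[docid] = rel
    return {
        qid: {docid for docid, rel in docs.items() if rel > 0} for qid, docs in judgements.items()
    }


def write_qrel(path: str | Path, qrel: Qrel) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for qid in sorted(qrel):
            for docid in sorted(qrel[qid]):
                fh.write(f"{qid} 0 {docid} 1\n")
    return path


def load_run(path: str | Path) -> Run:
    """Read a TREC run file; per query, order by descending score then rank."""
    rows: dict[str, list[tuple[float, int, str]]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 'qid Q0 docid rank score tag'")
        qid, _, docid, rank, score, _tag = parts
        rows.setdefault(qid, []).append((-float(score), int(rank), docid))
    run: Run = {}
    for qid in rows:
        run[qid] = [docid for _, _, docid in sorted(rows[qid])]
    return run


def _query_metrics(ranked: list[str], relevant: set[str]) -> QueryMetrics:
    n_rel = len(relevant)
    hits = 0
    ap_sum = 0.0
    rr = 0.0
    interp_p0 = 0.0
    p1 = 0.0
    p10_hits = 0
    for rank, docid in enumerate(ranked, start=1):
        if docid in relevant:
            hits += 1
            precision_here = hits / rank
            ap_sum += precision_here
            interp_p0 = max(interp_p0, precision_here)
            if rr == 0.0:
                rr = 1.0 / rank
            if rank == 1:
                p1 = 1.0
            if rank <= 10:
                p10_hits += 1
    return QueryMetrics(
        p_at_1=p1,
        p_at_10=p10_hits / 10.0,
        ap=ap_sum / n_rel if n_rel else 0.0,
        rr=rr,
        interp_p0=interp_p0,
    )


def compute_metrics(run: Run, qrel: Qrel) -> MetricsReport:
    """Evaluate every run query that has judgements.

    Queries absent from the qrel, or with an empty relevant set, are skipped
    with a warning and excluded from the means.  Duplicate docids within one
    ranked list violate the run contract and raise ``ValueError``.
    """
    per_query: dict[str, QueryMetrics] = {}
    for qid in sorted(run):
        ranked = run[qid]
        if len(set(ranked)) != len(ranked):
            raise ValueError(f"duplicate docid in ranked list of query {qid}")
        relevant = qrel.get(qid)
        if relevant is None:
            logger.warning("query %s has no judgements; skipped", qid)
            continue
        if not relevant:
            logger.warning("query %s has an empty relevant set; excluded from means", qid)
            continue
        per_query[qid] = _query_metrics(ranked, relevant)
    return MetricsReport(per_query=per_query)


def relative_gain(new_value: float, base_value: float) -> float:
    """Percent gain of ``new_value`` over ``base_value``.

    ``100 * (new - base) / base``, rounded half-to-even to one decimal.
    A zero (or negative) baseline has no defined gain and raises.
    """
    if base_value <= 0:
        raise ValueError("relative gain is undefined for a non-positive baseline")
    return round(100.0 * (new_value - base_value) / base_value, 1)
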