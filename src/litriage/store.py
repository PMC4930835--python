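"""The annotation store: keyed persistence of annotation tuples.

Annotations computed ahead of time are kept in a pmid-keyed store and served
as a JSON payload with exactly the fields ``{"error", "pmid", "result"}``,
each result object carrying ``{"termid", "tf", "form"}``.  The store also
answers the per-axis density questions the ranking function asks: how many
distinct terms of an axis appear in a document (the *matching index size*)
and their summed term frequency.

The backend is an in-memory map with JSON file persistence; the contract is
keyed retrieval only.  Axis membership of a term id is resolved through an
explicit ``term_id -> axis`` map built from the lexicons, never from
identifier prefixes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .ner import AnnotationRecord


@dataclass(frozen=True)
class AxisProfile:
    """Entity-density summary of one document for one axis."""

    pmid: str
    axis: str
    matching_index_size: int
    total_tf: int


class AnnotationStore:
    """pmid-keyed map of annotation records with axis lookups."""

    def __init__(self, axis_map: dict[str, str] | None = None) -> None:
        #: term_id -> axis tag; used by axis_profile.
        self.axis_map: dict[str, str] = dict(axis_map or {})
        self._records: dict[str, dict[tuple[str, str], AnnotationRecord]] = {}

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._records

    def __len__(self) -> int:
        return len(self._records)

    def pmids(self) -> list[str]:
        return sorted(self._records)

    def fetch(self, pmid: str) -> list[AnnotationRecord]:
        """Records for ``pmid`` in canonical (termid, form) order; [] if absent."""
        recs = self._records.get(pmid, {})
        return [recs[key] for key in sorted(recs)]

    def save(self, path: str | Path) -> None:
        payload = {
            "axis_map": {tid: self.axis_map[tid] for tid in sorted(self.axis_map)},
            "records": [
                {"pmid": r.pmid, "termid": r.term_id, "tf": r.tf, "form": r.form}
                for pmid in sorted(self._records)
                for r in self.fetch(pmid)
            ],
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationStore":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        store = cls(axis_map=payload.get("axis_map", {}))
        put_records(
            store,
            [
                AnnotationRecord(pmid=r["pmid"], term_id=r["termid"], tf=r["tf"], form=r["form"])
                for r in payload.get("records", [])
            ],
        )
        return store


def put_records(store: AnnotationStore, records: Iterable[AnnotationRecord]) -> AnnotationStore:
    """Insert records; re-inserting a (pmid, termid, form) key replaces the old one."""
    for rec in records:
        if rec.tf < 1:
            raise ValueError(f"malformed record: tf={rec.tf} for {rec.pmid}/{rec.term_id}")
        store._records.setdefault(rec.pmid, {})[(rec.term_id, rec.form)] = rec
    return store


def fetch_json(store: AnnotationStore, pmid: str) -> dict:
    """JSON-ready payload for ``pmid``.

    Always has exactly the keys ``error``, ``pmid``, ``result``; ``error`` is
    the empty string on success and a message (with an empty result) for an
    unknown pmid — a miss is a payload, not an exception.
    """
    if pmid not in store:
        return {"error": f"no annotations stored for pmid {pmid}", "pmid": pmid, "result": []}
    return {
        "error": "",
        "pmid": pmid,
        "result": [
            {"termid": rec.term_id, "tf": rec.tf, "form": rec.form} for rec in store.fetch(pmid)
        ],
    }


def payload_to_json(payload: dict) -> str:
    """Canonical serialization of a fetch payload (deterministic, UTF-8)."""
    return json.dumps(payload, ensure_ascii=False, separators=(", ", ": "))


def axis_profile(store: AnnotationStore, pmid: str, axis: str) -> AxisProfile:
    """Density profile of ``pmid`` for ``axis``; a zero profile if absent.

    Only records whose term id maps to ``axis`` in the store's axis map are
    counted.
    """
    term_tf: dict[str, int] = {}
    for rec in store.fetch(pmid):
        if store.axis_map.get(rec.term_id) == axis:
            term_tf[rec.term_id] = term_tf.get(rec.term_id, 0) + rec.tf
    return AxisProfile(
        pmid=pmid,
        axis=axis,
        matching_index_size=len(term_tf),
        total_tf=sum(term_tf.values()),
    )
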