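"""Controlled-vocabulary loading, refinement and lexicon construction.

The triage pipeline annotates abstracts against several terminologies, each
mapped to a *curation axis*: diseases (an NCIt-style thesaurus), the Gene
Ontology sub-ontologies (molecular function, biological process, cellular
component), evidence codes, species and chemical compounds.  Raw
terminologies contain surfaces that are poison for dictionary matching —
three-letter abbreviations such as "CAN" (Chronic Allograft Nephropathy) that
collide with ordinary English.  A :class:`RefinementPolicy` therefore drops
surfaces shorter than a minimum character length and surfaces equal to a
stopword before the lexicon is built.

Two input dialects are supported: OBO 1.2 flat files (GO/ECO style, parsed
with ``obonet``) and a simple tabular export
(``term_id<TAB>preferred_name<TAB>synonym<TAB>syn_type``) for thesauri that
ship pre-flattened, e.g. an NCIt export pre-merged with MeSH/UMLS synonyms.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

from .text import normalize_surface

logger = logging.getLogger(__name__)

#: Closed set of synonym types.  EXACT/NARROW/RELATED/BROAD follow the OBO
#: synonym scopes; PREFERRED and ABBREVIATION occur in tabular exports.
SYN_TYPES = frozenset({"EXACT", "NARROW", "RELATED", "BROAD", "PREFERRED", "ABBREVIATION"})

#: Known curation axes / entity classes.
AXES = ("DISEASES", "GO_MF", "GO_BP", "GO_CC", "ECO", "SPECIES", "CHEBI")

#: GO namespace line -> axis tag.
GO_NAMESPACE_AXES = {
    "molecular_function": "GO_MF",
    "biological_process": "GO_BP",
    "cellular_component": "GO_CC",
}

_OBO_SYNONYM_RE = re.compile(r'^"(?P<surface>.*)"\s*(?P<scope>EXACT|NARROW|RELATED|BROAD)?')


@dataclass(frozen=True)
class SynonymRecord:
    """One synonym surface with its declared scope."""

    surface: str
    syn_type: str = "EXACT"

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("synonym surface must be non-empty")
        if self.syn_type not in SYN_TYPES:
            raise ValueError(f"unknown synonym type {self.syn_type!r}; expected one of {sorted(SYN_TYPES)}")


@dataclass(frozen=True)
class TermEntry:
    """A vocabulary term: identifier, preferred name, synonyms, axis."""

    term_id: str
    preferred_name: str
    synonyms: tuple[SynonymRecord, ...] = ()
    axis: str | None = None

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if self.axis is not None and self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}; expected one of {AXES}")


@dataclass
class Vocabulary:
    """A named collection of terms; ``axis`` is None for mixed ontologies."""

    name: str
    axis: str | None = None
    entries: dict[str, TermEntry] = field(default_factory=dict)

    def add(self, entry: TermEntry) -> None:
        if entry.term_id in self.entries:
            raise ValueError(f"duplicate term_id {entry.term_id!r} in vocabulary {self.name!r}")
        self.entries[entry.term_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())


@dataclass(frozen=True)
class RefinementPolicy:
    """Surface filters applied before a vocabulary becomes matchable.

    ``min_surface_length`` counts characters of the raw surface, before
    normalization, so "CAN" (3 chars) is dropped at the default of 4.
    ``included_syn_types`` defaults to EXACT/NARROW/RELATED plus the tabular
    PREFERRED/ABBREVIATION rows; BROAD synonyms are excluded by default
    because broader surfaces inflate false positives.
    """

    stopword_list: frozenset[str] = field(default_factory=frozenset)
    min_surface_length: int = 4
    included_syn_types: frozenset[str] = frozenset(
        {"EXACT", "NARROW", "RELATED", "PREFERRED", "ABBREVIATION"}
    )

    def __post_init__(self) -> None:
        if self.min_surface_length < 1:
            raise ValueError("min_surface_length must be >= 1")
        unknown = self.included_syn_types - SYN_TYPES
        if unknown:
            raise ValueError(f"unknown synonym types in policy: {sorted(unknown)}")

    def retains(self, raw_surface: str) -> bool:
        """Whether ``raw_surface`` survives the length and stopword filters."""
        if len(raw_surface) < self.min_surface_length:
            return False
        return raw_surface.lower() not in self.stopword_list


class SurfaceProvenance(NamedTuple):
    term_id: str
    original_surface: str
    syn_type: str


@dataclass
class Lexicon:
    """Matchable dictionary for one axis.

    ``surface_map`` maps normalized surfaces (see :mod:`litriage.text`) to the
    set of term identifiers they denote; ``provenance`` records which raw
    surface and synonym type produced each normalized key.
    """

    axis: str | None
    surface_map: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, list[SurfaceProvenance]] = field(default_factory=dict)

    @property
    def max_tokens(self) -> int:
        """Longest surface length in tokens (0 for an empty lexicon)."""
        return max((key.count(" ") + 1 for key in self.surface_map), default=0)

    def save(self, path: str | Path) -> None:
        payload = {
            "axis": self.axis,
            "surfaces": {
                key: {
                    "term_ids": sorted(self.surface_map[key]),
                    "provenance": [list(p) for p in self.provenance.get(key, [])],
                }
                for key in sorted(self.surface_map)
            },
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Lexicon":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        lex = cls(axis=payload["axis"])
        for key, info in payload["surfaces"].items():
            lex.surface_map[key] = set(info["term_ids"])
            lex.provenance[key] = [SurfaceProvenance(*p) for p in info["provenance"]]
        return lex

    def axis_map(self) -> dict[str, str]:
        """term_id -> axis for every term in this lexicon."""
        if self.axis is None:
            return {}
        return {tid: self.axis for ids in self.surface_map.values() for tid in ids}


class LexiconStats(NamedTuple):
    surfaces: int
    terms: int


def default_stopwords() -> frozenset[str]:
    """The packaged list of frequent general-English words, lowercased."""
    text = resources.files("litriage.data").joinpath("stopwords.txt").read_text(encoding="utf-8")
    return frozenset(
        line.strip().lower() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def _parse_obo_synonym(raw: str) -> SynonymRecord | None:
    m = _OBO_SYNONYM_RE.match(raw.strip())
    if m is None or not m.group("surface"):
        return None
    return SynonymRecord(surface=m.group("surface"), syn_type=m.group("scope") or "RELATED")


def load_vocabulary(
    path: str | Path,
    format: str = "obo",
    axis_filter: str | None = None,
    axis: str | None = None,
    name: str | None = None,
) -> Vocabulary:
    """Load a vocabulary from an OBO or tabular file.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"obo"`` or ``"tabular"``.
    axis_filter:
        Restrict an OBO ontology to one axis via its ``namespace`` lines
        (e.g. ``GO_BP``); terms from other namespaces are skipped.  Terms with
        a namespace that maps to no known axis are skipped with a warning.
    axis:
        Axis tag assigned to terms with no namespace of their own (tabular
        files, or namespace-less OBO ontologies such as ECO subsets).
    name:
        Vocabulary name; defaults to the file stem.

    Obsolete OBO terms are skipped.  Malformed tabular rows raise a
    ``ValueError`` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"vocabulary file not found: {path}")
    if format == "obo":
        return _load_obo(path, axis_filter=axis_filter, axis=axis, name=name)
    if format == "tabular":
        return _load_tabular(path, axis=axis or axis_filter, name=name)
    raise ValueError(f"unknown vocabulary format {format!r}; expected 'obo' or 'tabular'")


def _load_obo(path: Path, axis_filter: str | None, axis: str | None, name: str | None) -> Vocabulary:
    import obonet

    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - normalize third-party parse errors
        raise ValueError(f"malformed OBO file {path}: {exc}") from exc

    vocab = Vocabulary(name=name or path.stem, axis=axis_filter or axis)
    for term_id, data in sorted(graph.nodes(data=True)):
        if "name" not in data:
            # dangling is_a target, not a term stanza of this file
            continue
        namespace = data.get("namespace")
        term_axis = GO_NAMESPACE_AXES.get(namespace) if namespace else axis
        if axis_filter is not None:
            if term_axis is None:
                logger.warning("term %s: namespace %r maps to no known axis; skipped", term_id, namespace)
                continue
            if term_axis != axis_filter:
                continue
        synonyms = []
        for raw in data.get("synonym", []):
            rec = _parse_obo_synonym(raw)
            if rec is None:
                raise ValueError(f"malformed synonym line for term {term_id} in {path}: {raw!r}")
            synonyms.append(rec)
        vocab.add(
            TermEntry(
                term_id=term_id,
                preferred_name=data.get("name", ""),
                synonyms=tuple(synonyms),
                axis=term_axis,
            )
        )
    return vocab


_TABULAR_COLUMNS = ["term_id", "preferred_name", "synonym", "syn_type"]


def _load_tabular(path: Path, axis: str | None, name: str | None) -> Vocabulary:
    vocab = Vocabulary(name=name or path.stem, axis=axis)
    preferred: dict[str, str] = {}
    synonyms: dict[str, list[SynonymRecord]] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return vocab
        if [h.strip() for h in header] != _TABULAR_COLUMNS:
            raise ValueError(f"{path}:1: expected header {_TABULAR_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(row)}")
            term_id, pref, syn, syn_type = (c.strip() for c in row)
            if not term_id:
                raise ValueError(f"{path}:{lineno}: empty term_id")
            preferred.setdefault(term_id, pref)
            if syn:
                if syn_type not in SYN_TYPES:
                    raise ValueError(f"{path}:{lineno}: unknown synonym type {syn_type!r}")
                synonyms.setdefault(term_id, []).append(SynonymRecord(surface=syn, syn_type=syn_type))
    for term_id in preferred:
        vocab.add(
            TermEntry(
                term_id=term_id,
                preferred_name=preferred[term_id],
                synonyms=tuple(synonyms.get(term_id, [])),
                axis=axis,
            )
        )
    return vocab


def build_lexicon(vocab: Vocabulary, policy: RefinementPolicy) -> Lexicon:
    """Apply ``policy`` to ``vocab`` and return the matchable lexicon.

    Preferred names are always candidate surfaces; synonyms only if their
    type is in ``policy.included_syn_types``.  Every candidate must pass the
    length and stopword filters and normalize to a non-empty token sequence.
    A vocabulary yielding zero retainable surfaces produces an empty lexicon
    with a warning, not an error.
    """
    lex = Lexicon(axis=vocab.axis)
    for entry in sorted(vocab, key=lambda e: e.term_id):
        candidates: list[tuple[str, str]] = [(entry.preferred_name, "PREFERRED")]
        candidates += [
            (syn.surface, syn.syn_type)
            for syn in entry.synonyms
            if syn.syn_type in policy.included_syn_types
        ]
        for raw, syn_type in candidates:
            if not raw or not policy.retains(raw):
                continue
            key = normalize_surface(raw)
            if not key:
                continue
            lex.surface_map.setdefault(key, set()).add(entry.term_id)
            lex.provenance.setdefault(key, []).append(SurfaceProvenance(entry.term_id, raw, syn_type))
    if vocab.entries and not lex.surface_map:
        logger.warning("vocabulary %r yielded no retainable surfaces under the policy", vocab.name)
    return lex


def vocab_stats(lexicon: Lexicon) -> LexiconStats:
    """Retained-surface and distinct-term counts of a built lexicon."""
    terms: set[str] = set()
    for ids in lexicon.surface_map.values():
        terms.update(ids)
    return LexiconStats(surfaces=len(lexicon.surface_map), terms=len(terms))
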