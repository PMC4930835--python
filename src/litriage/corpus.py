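"""Document collection: titles, abstracts and the metadata triage needs.

Two on-disk formats are read: MEDLINE/PubMed XML (``PubmedArticleSet``
dialect, the fields the method actually uses: PMID, ArticleTitle,
AbstractText, PubDate/Year, PublicationTypeList) and a JSONL interchange
format with one ``{"pmid","title","abstract","year","pub_types"}`` object per
line.  JSONL is the canonical internal format; XML input is converted on
read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)


@dataclass
class Document:
    """One citation: identifier, title, abstract and filter metadata."""

    pmid: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    pub_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.year is not None and self.year < 1800:
            raise ValueError(f"implausible publication year {self.year} for pmid {self.pmid}")
        self.pub_types = frozenset(self.pub_types)


@dataclass
class Corpus:
    """pmid-keyed document collection; duplicate pmids are rejected."""

    documents: dict[str, Document] = field(default_factory=dict)

    def add(self, doc: Document) -> bool:
        """Add ``doc``; returns False (with a warning) on a duplicate pmid."""
        if doc.pmid in self.documents:
            logger.warning("duplicate pmid %s: later record rejected", doc.pmid)
            return False
        self.documents[doc.pmid] = doc
        return True

    def __len__(self) -> int:
        return len(self.documents)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self.documents

    def __getitem__(self, pmid: str) -> Document:
        return self.documents[pmid]

    def __iter__(self):
        return iter(self.documents.values())


def read_documents(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus from ``path`` in ``jsonl`` or ``medline_xml`` format.

    Records lacking a pmid are rejected with a warning; a missing abstract
    becomes the empty string; publication types are preserved verbatim.
    Malformed records raise ``ValueError`` naming the record index.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"corpus file not found: {path}")
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "medline_xml":
        return _read_medline_xml(path)
    raise ValueError(f"unknown corpus format {format!r}; expected 'jsonl' or 'medline_xml'")


def _read_jsonl(path: Path) -> Corpus:
    corpus = Corpus()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
            if not rec.get("pmid"):
                logger.warning("%s:%d: record lacks a pmid; rejected", path, lineno)
                continue
            corpus.add(
                Document(
                    pmid=str(rec["pmid"]),
                    title=rec.get("title", "") or "",
                    abstract=rec.get("abstract", "") or "",
                    year=rec.get("year"),
                    pub_types=frozenset(rec.get("pub_types", [])),
                )
            )
    return corpus


def _read_medline_xml(path: Path) -> Corpus:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    corpus = Corpus()
    for i, article in enumerate(tree.iter("PubmedArticle"), start=1):
        pmid = article.findtext(".//PMID")
        if not pmid:
            logger.warning("%s: PubmedArticle #%d lacks a PMID; rejected", path, i)
            continue
        title = article.findtext(".//ArticleTitle") or ""
        # AbstractText may repeat (structured abstracts); join the pieces.
        abstract = " ".join(
            el.text for el in article.findall(".//Abstract/AbstractText") if el.text
        )
        year = _extract_year(article)
        pub_types = frozenset(
            el.text for el in article.findall(".//PublicationTypeList/PublicationType") if el.text
        )
        corpus.add(Document(pmid=pmid, title=title, abstract=abstract, year=year, pub_types=pub_types))
    return corpus


def _extract_year(article: etree._Element) -> int | None:
    year_text = article.findtext(".//PubDate/Year")
    if year_text and year_text.isdigit():
        return int(year_text)
    # MedlineDate fallback, e.g. "1998 Dec-1999 Jan".
    medline_date = article.findtext(".//PubDate/MedlineDate") or ""
    for token in medline_date.replace("-", " ").split():
        if token.isdigit() and len(token) == 4:
            return int(token)
    return None


def write_documents(corpus: Corpus, path: str | Path) -> Path:
    """Write ``corpus`` as JSONL; round-trips field-for-field via ``read_documents``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for pmid in sorted(corpus.documents):
            doc = corpus.documents[pmid]
            rec = {
                "pmid": doc.pmid,
                "title": doc.title,
                "abstract": doc.abstract,
                "year": doc.year,
                "pub_types": sorted(doc.pub_types),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return path
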