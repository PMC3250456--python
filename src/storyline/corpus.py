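"""Corpus ingestion, review pruning, seed labeling, and start-end pair construction.

Reads collections of biomedical abstracts from PubMed/MEDLINE XML exports or
from a one-record-per-line JSONL dialect, drops records missing a title,
abstract, or controlled-vocabulary (MeSH) terms, removes review articles
(they act as "lowest common denominator" hubs that short-circuit stories),
tags documents with seed molecule labels from user keyword lists, and builds
the term-disjoint (start, end) document pairs the story search runs between.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from lxml import etree


class FormatError(ValueError):
    """Raised when an input file does not parse in the declared dialect."""


class ConfigurationError(ValueError):
    """Raised for invalid user configuration (e.g. an empty keyword set)."""


# Abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = (
    "e.g", "i.e", "et al", "cf", "vs", "approx", "fig", "figs", "dr",
    "sp", "spp", "no", "vol", "ca",
)

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split abstract text into sentences.

    Splits at sentence-final punctuation followed by whitespace and an
    uppercase letter (or digit), guarded by a small abbreviation list so
    "e.g. Protein" or "et al. Showed" do not split.
    """
    if not text or not text.strip():
        return []
    pieces: list[str] = []
    buffer = ""
    for chunk in _SENT_BOUNDARY.split(text.strip()):
        candidate = (buffer + " " + chunk).strip() if buffer else chunk
        head = candidate.rstrip(".!?").lower()
        if candidate.endswith(".") and any(
            head.endswith(a) for a in _ABBREVIATIONS
        ):
            buffer = candidate
        else:
            pieces.append(candidate)
            buffer = ""
    if buffer:
        pieces.append(buffer)
    return [p for p in (s.strip() for s in pieces) if p]


@dataclass
class Document:
    """One abstract: identifier, title, ordered sentences, MeSH terms, types.

    ``seed_label`` is the (at most one) molecule tag assigned by
    :func:`label_seeds`.
    """

    doc_id: str
    title: str
    sentences: list[str]
    mesh_terms: list[str] = field(default_factory=list)
    publication_types: list[str] = field(default_factory=list)
    seed_label: str | None = None

    @property
    def abstract(self) -> str:
        return " ".join(self.sentences)


@dataclass
class Corpus:
    """A review-pruned document collection plus its filter provenance log."""

    documents: list[Document]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def get(self, doc_id: str) -> Document:
        return self._index()[doc_id]

    def _index(self) -> dict[str, Document]:
        if not hasattr(self, "_by_id") or len(self._by_id) != len(self.documents):
            self._by_id = {d.doc_id: d for d in self.documents}
        return self._by_id


@dataclass(frozen=True)
class SeedPair:
    """A (start, end) document pair with no overlap of modeled terms."""

    start_id: str
    end_id: str


_REVIEW_TOKEN = re.compile(r"\breview\b", re.IGNORECASE)


def review_filter(doc: Document) -> bool:
    """True iff the document should be excluded as a review article.

    A document is a review when its publication types contain a review type,
    its title contains the token "review" (token-level, so "reviewed" does
    not match), or any sentence contains the phrase "this review". Usages
    such as "is reviewed" alone do not flag a document.
    """
    if any("review" in t.lower() for t in doc.publication_types):
        return True
    if _REVIEW_TOKEN.search(doc.title):
        return True
    return any("this review" in s.lower() for s in doc.sentences)


def _admit(raw: dict, drops: dict[str, int]) -> Document | None:
    """Build a Document from a raw record, or count why it was dropped."""
    title = (raw.get("title") or "").strip()
    abstract = (raw.get("abstract") or "").strip()
    mesh = [m for m in (raw.get("mesh_terms") or []) if m]
    if not title:
        drops["missing_title"] += 1
        return None
    if not abstract:
        drops["missing_abstract"] += 1
        return None
    if not mesh:
        drops["missing_mesh"] += 1
        return None
    sentences = split_sentences(abstract)
    if not sentences:
        drops["missing_abstract"] += 1
        return None
    doc = Document(
        doc_id=str(raw["doc_id"]),
        title=title,
        sentences=sentences,
        mesh_terms=list(mesh),
        publication_types=list(raw.get("publication_types") or []),
    )
    if review_filter(doc):
        drops["review"] += 1
        return None
    return doc


def _iter_jsonl(path: str) -> Iterable[dict]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(
                    f"{path}: line {lineno} is not valid JSON: {exc}"
                ) from exc
            if "doc_id" not in raw:
                raise FormatError(f"{path}: line {lineno} has no 'doc_id'")
            yield raw


def _iter_medline_xml(path: str) -> Iterable[dict]:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from exc
    articles = tree.findall(".//PubmedArticle")
    if not articles:
        articles = tree.findall(".//MedlineCitation")
    for pos, art in enumerate(articles, start=1):
        cit = art.find("MedlineCitation")
        if cit is None and art.tag == "MedlineCitation":
            cit = art
        if cit is None:
            raise FormatError(f"{path}: record {pos} has no MedlineCitation")
        pmid = cit.findtext("PMID")
        if not pmid:
            raise FormatError(f"{path}: record {pos} has no PMID")
        abstract = " ".join(
            (t.text or "").strip()
            for t in cit.findall(".//Abstract/AbstractText")
        ).strip()
        yield {
            "doc_id": pmid.strip(),
            "title": (cit.findtext(".//Article/ArticleTitle") or "").strip(),
            "abstract": abstract,
            "mesh_terms": [
                (d.text or "").strip()
                for d in cit.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            ],
            "publication_types": [
                (p.text or "").strip()
                for p in cit.findall(".//PublicationTypeList/PublicationType")
            ],
        }


def read_corpus(path: str, format: str = "jsonl") -> Corpus:
    """Read a corpus from ``path`` in the named dialect.

    ``format`` is ``"jsonl"`` (one document object per line with fields
    doc_id/title/abstract/mesh_terms/publication_types) or ``"medline-xml"``
    (a PubMed XML export). Records missing a title, abstract, or MeSH terms
    are dropped and counted in provenance, as are review articles.
    """
    if format == "jsonl":
        records = _iter_jsonl(path)
    elif format == "medline-xml":
        records = _iter_medline_xml(path)
    else:
        raise ConfigurationError(f"unknown corpus format: {format!r}")

    drops = {"missing_title": 0, "missing_abstract": 0, "missing_mesh": 0,
             "review": 0}
    documents: list[Document] = []
    seen: set[str] = set()
    n_records = 0
    for raw in records:
        n_records += 1
        doc = _admit(raw, drops)
        if doc is None:
            continue
        if doc.doc_id in seen:
            raise FormatError(f"{path}: duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        documents.append(doc)
    return Corpus(
        documents=documents,
        provenance={
            "source": path,
            "format": format,
            "records_read": n_records,
            "drops": drops,
        },
    )


def corpus_from_records(records: Sequence[dict]) -> Corpus:
    """Build a corpus from in-memory raw records (same dialect as JSONL)."""
    drops = {"missing_title": 0, "missing_abstract": 0, "missing_mesh": 0,
             "review": 0}
    docs = []
    for raw in records:
        doc = _admit(raw, drops)
        if doc is not None:
            docs.append(doc)
    return Corpus(documents=docs, provenance={
        "source": "<memory>", "format": "records",
        "records_read": len(records), "drops": drops,
    })


def _keyword_hits(doc: Document, keywords: Sequence[str]) -> int:
    text = (doc.title + " " + doc.abstract).lower()
    return sum(text.count(kw.lower()) for kw in keywords)


def label_seeds(
    corpus: Corpus,
    keyword_sets: Mapping[str, Sequence[str]],
    cap: int = 700,
) -> Corpus:
    """Tag documents with seed labels from keyword lists, in place.

    A document receives label L when any keyword of L occurs
    (case-insensitively) in its title or abstract. Each label keeps at most
    ``cap`` documents, ranked by total keyword match count (ties broken by
    corpus order), and no document carries more than one label: a document
    matching several labels gets the first match in the keyword-set order.
    """
    if cap < 1:
        raise ConfigurationError("cap must be >= 1")
    for label, kws in keyword_sets.items():
        if not kws:
            raise ConfigurationError(f"empty keyword set for label {label!r}")
    for doc in corpus:
        doc.seed_label = None
    taken: set[str] = set()
    for label, kws in keyword_sets.items():
        scored = []
        for pos, doc in enumerate(corpus):
            if doc.doc_id in taken:
                continue
            hits = _keyword_hits(doc, kws)
            if hits > 0:
                scored.append((-hits, pos, doc))
        scored.sort(key=lambda t: (t[0], t[1]))
        for _, _, doc in scored[:cap]:
            doc.seed_label = label
            taken.add(doc.doc_id)
    return corpus


def make_seed_pairs(
    corpus: Corpus,
    start_labels: Iterable[str],
    end_labels: Iterable[str],
    vectors: Mapping[str, "TermVector"],  # noqa: F821 - vector_model type
) -> list[SeedPair]:
    """All term-disjoint (start, end) combinations, deterministically ordered.

    The disjointness is over the modeled term sets (the support of each
    document's term vector), which guarantees the searched connection is not
    already present at the endpoints.
    """
    start_set = set(start_labels)
    end_set = set(end_labels)
    starts = [d for d in corpus if d.seed_label in start_set]
    ends = [d for d in corpus if d.seed_label in end_set]
    pairs: list[SeedPair] = []
    for s in starts:
        s_terms = set(vectors[s.doc_id].weights) if s.doc_id in vectors else set()
        for e in ends:
            if s.doc_id == e.doc_id:
                continue
            e_terms = set(vectors[e.doc_id].weights) if e.doc_id in vectors else set()
            if s_terms.isdisjoint(e_terms):
                pairs.append(SeedPair(s.doc_id, e.doc_id))
    pairs.sort(key=lambda p: (p.start_id, p.end_id))
    return pairs
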