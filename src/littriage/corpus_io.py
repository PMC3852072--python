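"""Corpus containers and I/O: PubMed XML ingestion and the labeled TSV format.

A :class:`Document` is one article record (id, title, abstract, MeSH
headings, optional relevance label); a :class:`Corpus` is an ordered list of
documents plus a free-text provenance note.  Labeled corpora are stored as
UTF-8 tab-separated files with a header row; tabs and newlines inside text
fields are backslash-escaped so the format round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from lxml import etree

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"
LABELS = (RELEVANT, IRRELEVANT)


class CorpusError(ValueError):
    """Raised for malformed corpora or corpus files."""


@dataclass(frozen=True)
class Document:
    """One article record.

    ``classification_text`` is the text the pipeline actually classifies:
    title, abstract and MeSH headings joined by single spaces, since a corpus
    entry carries all three.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: tuple[str, ...] = ()
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if self.label is not None and self.label not in LABELS:
            raise CorpusError(
                f"label must be one of {LABELS} or None, got {self.label!r}"
            )
        object.__setattr__(self, "mesh_terms", tuple(self.mesh_terms))

    @property
    def classification_text(self) -> str:
        parts = [self.title, self.abstract, " ".join(self.mesh_terms)]
        return " ".join(p for p in parts if p)


@dataclass
class Corpus:
    """Ordered collection of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.documents == other.documents

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    @property
    def labels(self) -> list[Optional[str]]:
        return [d.label for d in self.documents]

    def class_counts(self) -> dict[str, int]:
        counts = {RELEVANT: 0, IRRELEVANT: 0}
        for d in self.documents:
            if d.label is not None:
                counts[d.label] += 1
        return counts

    def is_fully_labeled(self) -> bool:
        return all(d.label is not None for d in self.documents)

    def subset(self, label: str) -> "Corpus":
        return Corpus(
            [d for d in self.documents if d.label == label],
            provenance=f"{self.provenance} [subset {label}]".strip(),
        )


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def parse_pubmed_xml(path: str | Path) -> tuple[Corpus, int]:
    """Parse a PubmedArticleSet XML file into an unlabeled corpus.

    Returns ``(corpus, n_missing_abstract)`` where the second element counts
    articles that carried no AbstractText element (they are kept with an
    empty abstract).  Articles without a PMID receive a deterministic
    surrogate id ``<filename>:<ordinal>``.

    Raises
    ------
    CorpusError
        If the XML is malformed (message includes the parser's position) or
        two articles share a PMID.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML in {path.name}: {exc}") from exc

    documents: list[Document] = []
    missing_abstract = 0
    for ordinal, article in enumerate(tree.iter("PubmedArticle"), start=1):
        pmid = article.findtext(".//MedlineCitation/PMID")
        if not pmid:
            pmid = f"{path.name}:{ordinal}"
        title = (article.findtext(".//Article/ArticleTitle") or "").strip()
        abstract_parts = [
            (node.text or "").strip()
            for node in article.findall(".//Article/Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abstract_parts if p)
        if not article.findall(".//Article/Abstract/AbstractText"):
            missing_abstract += 1
        mesh = tuple(
            (node.text or "").strip()
            for node in article.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if (node.text or "").strip()
        )
        documents.append(
            Document(doc_id=pmid, title=title, abstract=abstract, mesh_terms=mesh)
        )

    ids = [d.doc_id for d in documents]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CorpusError(f"duplicate PMID(s) in {path.name}: {sorted(dupes)}")
    return Corpus(documents, provenance=str(path)), missing_abstract


# ---------------------------------------------------------------------------
# Labeled corpus TSV
# ---------------------------------------------------------------------------

_HEADER = ["doc_id", "label", "title", "abstract", "mesh_terms"]


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace("\t", "\\t")
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def _unescape(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "r": "\r", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as tab-separated UTF-8 text (one document per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for doc in corpus:
            fields = [
                doc.doc_id,
                doc.label or "",
                _escape(doc.title),
                _escape(doc.abstract),
                _escape("|".join(doc.mesh_terms)),
            ]
            fh.write("\t".join(fields) + "\n")


def read_corpus(path: str | Path, require_labels: bool = False) -> Corpus:
    """Read a corpus TSV written by :func:`write_corpus`.

    With ``require_labels=True`` every row must carry a valid label; an
    unknown label token raises :class:`CorpusError` naming the row.
    """
    path = Path(path)
    documents: list[Document] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise CorpusError(
                f"{path.name}: unexpected header {header!r}; expected {_HEADER!r}"
            )
        for row_num, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_HEADER):
                raise CorpusError(
                    f"{path.name} row {row_num}: expected {len(_HEADER)} fields, "
                    f"got {len(fields)}"
                )
            doc_id, label, title, abstract, mesh = fields
            if label == "":
                if require_labels:
                    raise CorpusError(f"{path.name} row {row_num}: missing label")
                parsed_label = None
            elif label in LABELS:
                parsed_label = label
            else:
                raise CorpusError(
                    f"{path.name} row {row_num}: unknown label {label!r}"
                )
            mesh_terms = tuple(
                t for t in _unescape(mesh).split("|") if t
            )
            documents.append(
                Document(
                    doc_id=doc_id,
                    title=_unescape(title),
                    abstract=_unescape(abstract),
                    mesh_terms=mesh_terms,
                    label=parsed_label,
                )
            )
    return Corpus(documents, provenance=str(path))


def read_labeled_corpus(path: str | Path) -> Corpus:
    """Read a fully labeled training corpus (every row must carry a label)."""
    return read_corpus(path, require_labels=True)


def relabel(doc: Document, label: Optional[str]) -> Document:
    """Return a copy of ``doc`` with a new label."""
    return replace(doc, label=label)


def concat(corpora: Iterable[Corpus], provenance: str = "") -> Corpus:
    docs: list[Document] = []
    for c in corpora:
        docs.extend(c.documents)
    return Corpus(docs, provenance=provenance)
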