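"""Document-term matrix construction and Tf-Idf weighting.

The document-term matrix (DTM) holds raw term counts per document over a
fixed, lexicographically sorted vocabulary.  Tf-Idf weighting is
length-normalised term frequency times a log2 inverse document frequency
fitted on a stated reference corpus:

    weight(d, t) = count(d, t) / total_tokens(d) * log2(N_ref / df_ref(t))

Fitting idf on the training corpus only, and projecting query documents onto
the frozen training vocabulary, keeps evaluation free of information leaking
from the documents being classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .preprocess import TokenizedDocument


class VectorizeError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Ordered unique terms with a term -> column index mapping."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise VectorizeError("vocabulary terms must be unique")
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.terms)}
        )

    @classmethod
    def from_tokens(cls, tokenized: Sequence[TokenizedDocument]) -> "Vocabulary":
        terms = sorted({t for doc in tokenized for t in doc.tokens})
        return cls(tuple(terms))

    @property
    def term_index(self) -> dict[str, int]:
        return self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.term_index


@dataclass(frozen=True)
class DocTermMatrix:
    """Sparse non-negative integer counts, documents x terms."""

    counts: sp.csr_matrix
    doc_ids: tuple[str, ...]
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise VectorizeError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.doc_ids)} docs x {len(self.vocabulary)} terms"
            )
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise VectorizeError("doc_ids must be unique")

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    def document_frequency(self) -> np.ndarray:
        """Number of documents containing each term."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def row_token_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass(frozen=True)
class WeightedMatrix:
    """Tf-Idf weights sharing the source DTM's shape and labels."""

    weights: sp.csr_matrix
    doc_ids: tuple[str, ...]
    vocabulary: Vocabulary
    idf: np.ndarray  # per-term log2(N_ref / df_ref), 0 where df_ref == 0


def build_dtm(
    tokenized: Sequence[TokenizedDocument],
    vocabulary: Optional[Vocabulary] = None,
) -> DocTermMatrix:
    """Count terms per document.

    Without a vocabulary, one is built from the input (sorted unique tokens).
    With a vocabulary (projection mode, used at classification time), tokens
    outside it are silently dropped.
    """
    if not tokenized:
        raise VectorizeError("cannot build a DTM from an empty document list")
    if vocabulary is None:
        vocabulary = Vocabulary.from_tokens(tokenized)
    index = vocabulary.term_index
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for i, doc in enumerate(tokenized):
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in sorted(counts.items()):
            rows.append(i)
            cols.append(j)
            data.append(c)
    mat = sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(tokenized), len(vocabulary)),
        dtype=np.int64,
    )
    return DocTermMatrix(
        counts=mat,
        doc_ids=tuple(d.doc_id for d in tokenized),
        vocabulary=vocabulary,
    )


def compute_idf(reference: DocTermMatrix) -> np.ndarray:
    """log2(N / df) per term on the reference corpus; 0 for absent terms."""
    df = reference.document_frequency().astype(float)
    idf = np.zeros(len(reference.vocabulary))
    present = df > 0
    idf[present] = np.log2(reference.n_docs / df[present])
    return idf


def tfidf_transform(
    dtm: DocTermMatrix,
    reference: Optional[DocTermMatrix] = None,
    idf: Optional[np.ndarray] = None,
) -> WeightedMatrix:
    """Apply Tf-Idf weighting.

    The idf component comes from ``reference`` (default: the input itself) or
    from a precomputed ``idf`` vector fitted on the training corpus.  Rows
    with zero tokens stay zero; terms absent from the reference get weight 0.
    """
    if idf is not None and reference is not None:
        raise VectorizeError("give either a reference DTM or an idf vector, not both")
    if idf is None:
        if reference is None:
            reference = dtm
        elif reference.vocabulary.terms != dtm.vocabulary.terms:
            raise VectorizeError("reference vocabulary differs from DTM vocabulary")
        idf = compute_idf(reference)
    idf = np.asarray(idf, dtype=float)
    if idf.shape != (len(dtm.vocabulary),):
        raise VectorizeError("idf length does not match vocabulary size")

    totals = dtm.row_token_counts().astype(float)
    inv_totals = np.divide(
        1.0, totals, out=np.zeros_like(totals), where=totals > 0
    )
    tf = sp.diags(inv_totals) @ dtm.counts.astype(float)
    weights = (tf @ sp.diags(idf)).tocsr()
    weights.eliminate_zeros()
    return WeightedMatrix(
        weights=weights,
        doc_ids=dtm.doc_ids,
        vocabulary=dtm.vocabulary,
        idf=idf,
    )


def filter_sparse_terms(dtm: DocTermMatrix, max_sparsity: float) -> DocTermMatrix:
    """Drop terms absent from more than ``max_sparsity`` of the documents.

    ``max_sparsity=1.0`` keeps everything (the default behaviour of the
    pipeline, which retains rare terms).
    """
    if not 0 < max_sparsity <= 1:
        raise VectorizeError("max_sparsity must be in (0, 1]")
    df = dtm.document_frequency()
    absence = 1.0 - df / dtm.n_docs
    keep = np.flatnonzero(absence <= max_sparsity)
    if keep.size == 0:
        raise VectorizeError(
            "sparsity threshold removed every term; raise max_sparsity"
        )
    if keep.size == len(dtm.vocabulary):
        return dtm
    vocab = Vocabulary(tuple(dtm.vocabulary.terms[j] for j in keep))
    return DocTermMatrix(
        counts=dtm.counts[:, keep].tocsr(),
        doc_ids=dtm.doc_ids,
        vocabulary=vocab,
    )


# ---------------------------------------------------------------------------
# MatrixMarket export with sidecar label files
# ---------------------------------------------------------------------------

def write_matrix(dtm: DocTermMatrix, path: str | Path) -> None:
    """Write counts as MatrixMarket plus ``.doc_ids.txt`` / ``.vocab.txt`` sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), dtm.counts.tocoo())
    path.with_suffix(path.suffix + ".doc_ids.txt").write_text(
        "".join(f"{d}\n" for d in dtm.doc_ids), encoding="utf-8"
    )
    path.with_suffix(path.suffix + ".vocab.txt").write_text(
        "".join(f"{t}\n" for t in dtm.vocabulary.terms), encoding="utf-8"
    )


def read_matrix(path: str | Path) -> DocTermMatrix:
    path = Path(path)
    counts = sp.csr_matrix(scipy.io.mmread(str(path)), dtype=np.int64)
    doc_ids = tuple(
        path.with_suffix(path.suffix + ".doc_ids.txt")
        .read_text("utf-8")
        .splitlines()
    )
    terms = tuple(
        path.with_suffix(path.suffix + ".vocab.txt").read_text("utf-8").splitlines()
    )
    return DocTermMatrix(counts=counts, doc_ids=doc_ids, vocabulary=Vocabulary(terms))
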