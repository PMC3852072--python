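"""k-nearest-neighbor relevance scoring of abstracts.

A trained model freezes the preprocessing configuration, the training
vocabulary, the idf vector fitted on the training corpus, the Tf-Idf
training matrix and its labels.  New documents are embedded through exactly
the same chain, scored by the fraction of relevant documents among their k
nearest training rows, and returned as a ranked list from most to least
probable — eliminating the need for a static relevance threshold.

The default distance is cosine, the standard choice for Tf-Idf text
vectors: it compares term-usage direction and is insensitive to the
per-document weight norm.  Euclidean distance (the metric of classic k-NN
library routines) is available as a config option, but on Tf-Idf vectors it
is sensitive to systematic norm differences between classes — when one
class concentrates more of its token mass in down-weighted common terms,
Euclidean neighborhoods collapse onto the smaller-norm class regardless of
term overlap.

Distance ties that straddle the k-th position expand the neighbor set to all
rows tied with the k-th distance, and the score becomes the relevant
fraction of the expanded set; this makes the output deterministic and
independent of training-row order.  Exact ties between squared distances
arise in practice only from documents with identical token profiles.
"""

from __future__ import annotations

import json
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .corpus_io import Corpus, RELEVANT, IRRELEVANT
from .preprocess import PreprocessConfig, preprocess_corpus
from .vectorize import Vocabulary, WeightedMatrix, build_dtm, tfidf_transform

METRIC_EUCLIDEAN = "euclidean"
METRIC_COSINE = "cosine"
DEFAULT_METRIC = METRIC_COSINE

MODEL_FORMAT = "littriage-knn-model"
MODEL_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class KnnModel:
    training_weights: WeightedMatrix
    training_labels: tuple[str, ...]
    k: int
    preprocess_cfg: PreprocessConfig
    metric: str = DEFAULT_METRIC

    def __post_init__(self) -> None:
        n = self.training_weights.weights.shape[0]
        if len(self.training_labels) != n:
            raise ModelError("label vector length must equal training row count")
        if not 1 <= self.k <= n:
            raise ModelError(f"k={self.k} must be in [1, {n}]")
        if self.metric not in (METRIC_EUCLIDEAN, METRIC_COSINE):
            raise ModelError(f"unknown metric {self.metric!r}")

    @property
    def vocabulary(self) -> Vocabulary:
        return self.training_weights.vocabulary

    @property
    def idf(self) -> np.ndarray:
        return self.training_weights.idf

    @property
    def n_training(self) -> int:
        return self.training_weights.weights.shape[0]


@dataclass(frozen=True)
class RelevancePrediction:
    doc_id: str
    score: float  # relevant_neighbor_count / neighbor_count
    relevant_neighbor_count: int
    neighbor_count: int  # k, or more when distance ties straddle position k
    predicted_label: str
    zero_vector: bool = False  # document fully out-of-vocabulary


@dataclass(frozen=True)
class RankedList:
    """Predictions sorted by score descending, doc_id ascending within ties."""

    predictions: tuple[RelevancePrediction, ...]

    def __post_init__(self) -> None:
        scores = [p.score for p in self.predictions]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ModelError("ranked list scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)


def train(
    corpus: Corpus,
    k: int,
    cfg: Optional[PreprocessConfig] = None,
    metric: str = DEFAULT_METRIC,
) -> KnnModel:
    """Fit the embedding (vocabulary + idf) and freeze the training matrix.

    Requires a fully labeled corpus with both classes present and k <= n.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    if not corpus.is_fully_labeled():
        raise ModelError("training corpus must be fully labeled")
    counts = corpus.class_counts()
    if counts[RELEVANT] == 0 or counts[IRRELEVANT] == 0:
        raise ModelError(
            f"training corpus must contain both classes, got {counts}"
        )
    if k > len(corpus):
        raise ModelError(f"k={k} exceeds corpus size {len(corpus)}")
    tokenized = preprocess_corpus(corpus, cfg)
    dtm = build_dtm(tokenized)
    weighted = tfidf_transform(dtm)
    return KnnModel(
        training_weights=weighted,
        training_labels=tuple(corpus.labels),  # type: ignore[arg-type]
        k=k,
        preprocess_cfg=cfg,
        metric=metric,
    )


def embed(model: KnnModel, corpus: Corpus) -> WeightedMatrix:
    """Embed query documents exactly as the training corpus was embedded."""
    tokenized = preprocess_corpus(corpus, model.preprocess_cfg)
    dtm = build_dtm(tokenized, vocabulary=model.vocabulary)
    return tfidf_transform(dtm, idf=model.idf)


def pairwise_distances(
    queries: sp.csr_matrix, training: sp.csr_matrix, metric: str = DEFAULT_METRIC
) -> np.ndarray:
    """Pairwise distances, queries x training.

    Cosine returns 1 - cosine similarity; Euclidean returns the SQUARED
    distance (monotone in the metric, which is all neighbor ranking needs).
    A zero query row has cosine distance 1 to every training row.
    """
    if metric == METRIC_EUCLIDEAN:
        qn = np.asarray(queries.multiply(queries).sum(axis=1)).ravel()
        tn = np.asarray(training.multiply(training).sum(axis=1)).ravel()
        cross = (queries @ training.T).toarray()
        d2 = qn[:, None] - 2.0 * cross + tn[None, :]
        np.maximum(d2, 0.0, out=d2)
        return d2
    if metric == METRIC_COSINE:
        qn = np.sqrt(np.asarray(queries.multiply(queries).sum(axis=1)).ravel())
        tn = np.sqrt(np.asarray(training.multiply(training).sum(axis=1)).ravel())
        cross = (queries @ training.T).toarray()
        denom = np.outer(qn, tn)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, cross / denom, 0.0)
        return 1.0 - cos
    raise ModelError(f"unknown metric {metric!r}")


def neighbor_votes(
    dist_row: np.ndarray, labels_relevant: np.ndarray, k: int
) -> tuple[int, int]:
    """(relevant count, neighbor count) among the k nearest with tie expansion.

    All training rows whose distance equals the k-th smallest are included,
    so the vote is independent of row order.
    """
    order = np.argsort(dist_row, kind="stable")
    kth = dist_row[order[k - 1]]
    members = dist_row <= kth
    return int(labels_relevant[members].sum()), int(members.sum())


def score_queries(
    model: KnnModel, weighted: WeightedMatrix, k: Optional[int] = None
) -> list[RelevancePrediction]:
    """Score embedded query rows against the model's training matrix."""
    if k is None:
        k = model.k
    d2 = pairwise_distances(
        weighted.weights, model.training_weights.weights, model.metric
    )
    rel = np.array([lab == RELEVANT for lab in model.training_labels])
    zero_rows = np.asarray(weighted.weights.power(2).sum(axis=1)).ravel() == 0
    preds = []
    for i, doc_id in enumerate(weighted.doc_ids):
        m, size = neighbor_votes(d2[i], rel, k)
        score = m / size
        preds.append(
            RelevancePrediction(
                doc_id=doc_id,
                score=score,
                relevant_neighbor_count=m,
                neighbor_count=size,
                predicted_label=RELEVANT if score > 0.5 else IRRELEVANT,
                zero_vector=bool(zero_rows[i]),
            )
        )
    return preds


def classify(model: KnnModel, corpus: Corpus) -> RankedList:
    """Preprocess, embed and score a corpus; return the ranked output list.

    Documents that reduce to the zero vector (all tokens out of the training
    vocabulary) are legitimate and flagged with ``zero_vector=True``: under
    cosine they are equidistant from every training row, so tie expansion
    scores them with the global relevant fraction (the class prior); under
    Euclidean their neighbors are the smallest-norm training rows.
    """
    weighted = embed(model, corpus)
    preds = score_queries(model, weighted)
    ranked = sorted(preds, key=lambda p: (-p.score, p.doc_id))
    return RankedList(tuple(ranked))


def bin_by_neighbor_count(ranked: RankedList | Sequence[RelevancePrediction], k: int) -> np.ndarray:
    """Histogram of relevant-neighbor counts over 0..k (k+1 bins).

    With six neighbors this reproduces the seven-group partition of a
    classified abstract body (zero to six relevant neighbors).  Counts above
    k (possible only under tie expansion) land in the top bin.
    """
    hist = np.zeros(k + 1, dtype=np.int64)
    for p in ranked:
        hist[min(p.relevant_neighbor_count, k)] += 1
    return hist


# ---------------------------------------------------------------------------
# Serialization: single JSON archive with an embedded MatrixMarket matrix
# ---------------------------------------------------------------------------

def save_model(model: KnnModel, path: str | Path) -> None:
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, model.training_weights.weights.tocoo())
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "k": model.k,
        "metric": model.metric,
        "doc_ids": list(model.training_weights.doc_ids),
        "labels": list(model.training_labels),
        "vocabulary": list(model.vocabulary.terms),
        "idf": model.idf.tolist(),
        "preprocess": model.preprocess_cfg.to_dict(),
        "matrix_mtx": buf.getvalue().decode("ascii"),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> KnnModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != MODEL_FORMAT:
        raise ModelError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelError(f"unsupported model version {payload.get('version')}")
    mat = sp.csr_matrix(
        scipy.io.mmread(io.BytesIO(payload["matrix_mtx"].encode("ascii")))
    )
    weighted = WeightedMatrix(
        weights=mat,
        doc_ids=tuple(payload["doc_ids"]),
        vocabulary=Vocabulary(tuple(payload["vocabulary"])),
        idf=np.asarray(payload["idf"], dtype=float),
    )
    return KnnModel(
        training_weights=weighted,
        training_labels=tuple(payload["labels"]),
        k=int(payload["k"]),
        preprocess_cfg=PreprocessConfig.from_dict(payload["preprocess"]),
        metric=payload["metric"],
    )
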