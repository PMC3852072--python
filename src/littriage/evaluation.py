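"""Model selection and evaluation: stratified cross-validation over a
neighbor grid, confusion metrics, and learning curves.

All randomness is driven by explicit integer seeds; identical seeds yield
identical reports.  Within every cross-validation fold the vocabulary and
idf vector are fitted on the training split only, and test documents are
projected onto that frozen embedding — the evaluation therefore measures
the same pipeline that classifies genuinely new abstracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Corpus, CorpusError, RELEVANT, IRRELEVANT
from .preprocess import PreprocessConfig, preprocess_corpus
from .knn import DEFAULT_METRIC, pairwise_distances
from .vectorize import build_dtm, tfidf_transform


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion table and derived rates; "relevant" is the positive class.

    Rates with a zero denominator are NaN and flagged in ``undefined``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def compute_metrics(
    predicted: Sequence[str], truth: Sequence[str]
) -> EvalMetrics:
    """Accuracy, sensitivity (TPR on relevant) and specificity (TNR)."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if not predicted:
        raise ValueError("cannot compute metrics on empty label lists")
    tp = sum(p == RELEVANT and t == RELEVANT for p, t in zip(predicted, truth))
    fp = sum(p == RELEVANT and t == IRRELEVANT for p, t in zip(predicted, truth))
    fn = sum(p == IRRELEVANT and t == RELEVANT for p, t in zip(predicted, truth))
    tn = sum(p == IRRELEVANT and t == IRRELEVANT for p, t in zip(predicted, truth))
    undefined = []
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity, undefined = math.nan, undefined + ["sensitivity"]
    if tn + fp > 0:
        specificity = tn / (tn + fp)
    else:
        specificity, undefined = math.nan, undefined + ["specificity"]
    return EvalMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class MeanMetrics:
    accuracy: float
    sensitivity: float
    specificity: float


def _mean_metrics(metrics: Sequence[EvalMetrics]) -> MeanMetrics:
    return MeanMetrics(
        accuracy=float(np.mean([m.accuracy for m in metrics])),
        sensitivity=float(np.nanmean([m.sensitivity for m in metrics])),
        specificity=float(np.nanmean([m.specificity for m in metrics])),
    )


@dataclass(frozen=True)
class CvReport:
    k_grid: tuple[int, ...]
    per_k: dict[int, MeanMetrics]
    folds: int
    seed: int
    best_k: int  # smallest k attaining the maximal mean accuracy


@dataclass(frozen=True)
class LearningCurve:
    train_sizes: tuple[int, ...]
    per_size: dict[int, MeanMetrics]
    test_size: int
    replicates: int
    seed: int
    k: int


def stratified_folds(
    labels: Sequence[str], folds: int, seed: int
) -> list[np.ndarray]:
    """Partition indices into class-balanced test folds."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = list(labels)
    assignments: list[list[int]] = [[] for _ in range(folds)]
    rng = np.random.default_rng(seed)
    for cls in (RELEVANT, IRRELEVANT):
        idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
        if 0 < idx.size < folds:
            raise CorpusError(
                f"class {cls!r} has {idx.size} documents; cannot stratify "
                f"into {folds} folds"
            )
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, folds)):
            assignments[f].extend(chunk.tolist())
    return [np.array(sorted(a)) for a in assignments]


def _votes_over_grid(
    d2_row: np.ndarray, rel: np.ndarray, k_grid: Sequence[int]
) -> list[tuple[int, int]]:
    """(relevant, total) neighbor counts for every k, with tie expansion."""
    order = np.argsort(d2_row, kind="stable")
    ds = d2_row[order]
    relcum = np.cumsum(rel[order])
    out = []
    for k in k_grid:
        cnt = int(np.searchsorted(ds, ds[k - 1], side="right"))
        out.append((int(relcum[cnt - 1]), cnt))
    return out


def cross_validate(
    corpus: Corpus,
    k_grid: Optional[Sequence[int]] = None,
    folds: int = 5,
    seed: int = 0,
    cfg: Optional[PreprocessConfig] = None,
    metric: str = DEFAULT_METRIC,
) -> CvReport:
    """Stratified k-fold cross-validation over a neighbor-count grid.

    Default grid is 1..155 (capped at the smallest training-split size).
    Ties at the maximal mean accuracy resolve to the smallest k.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    if not corpus.is_fully_labeled():
        raise CorpusError("cross-validation requires a fully labeled corpus")
    labels = [d.label for d in corpus]
    fold_tests = stratified_folds(labels, folds, seed)
    min_train = min(len(corpus) - len(f) for f in fold_tests)
    if k_grid is None:
        k_grid = range(1, min(155, min_train) + 1)
    k_grid = tuple(int(k) for k in k_grid)
    if any(k < 1 for k in k_grid):
        raise ValueError("k_grid entries must be >= 1")
    if max(k_grid) > min_train:
        raise ValueError(
            f"k={max(k_grid)} exceeds smallest training-fold size {min_train}"
        )

    tokenized = preprocess_corpus(corpus, cfg)
    truth = np.array([lab == RELEVANT for lab in labels])
    fold_metrics: dict[int, list[EvalMetrics]] = {k: [] for k in k_grid}
    for test_idx in fold_tests:
        test_mask = np.zeros(len(corpus), dtype=bool)
        test_mask[test_idx] = True
        train_idx = np.flatnonzero(~test_mask)
        train_toks = [tokenized[i] for i in train_idx]
        test_toks = [tokenized[i] for i in test_idx]
        train_dtm = build_dtm(train_toks)
        train_w = tfidf_transform(train_dtm)
        test_dtm = build_dtm(test_toks, vocabulary=train_dtm.vocabulary)
        test_w = tfidf_transform(test_dtm, idf=train_w.idf)
        d2 = pairwise_distances(test_w.weights, train_w.weights, metric)
        rel_train = truth[train_idx].astype(np.int64)
        votes = [_votes_over_grid(d2[i], rel_train, k_grid) for i in range(len(test_idx))]
        truth_labels = [labels[i] for i in test_idx]
        for kpos, k in enumerate(k_grid):
            predicted = [
                RELEVANT if votes[i][kpos][0] / votes[i][kpos][1] > 0.5 else IRRELEVANT
                for i in range(len(test_idx))
            ]
            fold_metrics[k].append(compute_metrics(predicted, truth_labels))

    per_k = {k: _mean_metrics(ms) for k, ms in fold_metrics.items()}
    best_acc = max(m.accuracy for m in per_k.values())
    best_k = min(k for k in k_grid if per_k[k].accuracy == best_acc)
    return CvReport(
        k_grid=k_grid, per_k=per_k, folds=folds, seed=seed, best_k=best_k
    )


def _balanced_sample(
    by_class: dict[str, list[int]], n_per_class: int
) -> list[int]:
    return by_class[RELEVANT][:n_per_class] + by_class[IRRELEVANT][:n_per_class]


def learning_curve(
    corpus: Corpus,
    initial: int = 26,
    increment: int = 26,
    test_size: int = 50,
    seed: int = 0,
    replicates: int = 25,
    k: int = 6,
    cfg: Optional[PreprocessConfig] = None,
    max_size: Optional[int] = None,
    metric: str = DEFAULT_METRIC,
) -> LearningCurve:
    """Accuracy/sensitivity/specificity as the training corpus grows.

    Per replicate, a class-balanced test set of ``test_size`` documents is
    held fixed while class-balanced training sets grow from ``initial`` in
    steps of ``increment`` (each half relevant, half irrelevant).  The
    default protocol starts at 13+13 documents, grows in steps of 26 and
    fixes the test set at 25+25.  Metrics are averaged over replicates.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    for name, v in (("initial", initial), ("increment", increment), ("test_size", test_size)):
        if v <= 0 or v % 2:
            raise ValueError(f"{name} must be positive and even, got {v}")
    counts = corpus.class_counts()
    need = initial // 2 + test_size // 2
    if min(counts[RELEVANT], counts[IRRELEVANT]) < need:
        raise CorpusError(
            f"corpus too small: need at least {need} documents per class "
            f"for initial={initial} and test_size={test_size}, have {counts}"
        )
    pool_per_class = min(counts[RELEVANT], counts[IRRELEVANT]) - test_size // 2
    largest = 2 * pool_per_class
    if max_size is not None:
        largest = min(largest, max_size)
    sizes = tuple(range(initial, largest + 1, increment))

    tokenized = preprocess_corpus(corpus, cfg)
    labels = list(corpus.labels)
    size_metrics: dict[int, list[EvalMetrics]] = {s: [] for s in sizes}
    for r in range(replicates):
        rng = np.random.default_rng([seed, r])
        by_class: dict[str, list[int]] = {}
        for cls in (RELEVANT, IRRELEVANT):
            idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
            rng.shuffle(idx)
            by_class[cls] = idx.tolist()
        test_idx = (
            by_class[RELEVANT][: test_size // 2]
            + by_class[IRRELEVANT][: test_size // 2]
        )
        pool = {
            cls: by_class[cls][test_size // 2 :] for cls in (RELEVANT, IRRELEVANT)
        }
        test_toks = [tokenized[i] for i in test_idx]
        truth_labels = [labels[i] for i in test_idx]
        for s in sizes:
            train_idx = _balanced_sample(pool, s // 2)
            train_toks = [tokenized[i] for i in train_idx]
            train_dtm = build_dtm(train_toks)
            train_w = tfidf_transform(train_dtm)
            test_dtm = build_dtm(test_toks, vocabulary=train_dtm.vocabulary)
            test_w = tfidf_transform(test_dtm, idf=train_w.idf)
            d2 = pairwise_distances(test_w.weights, train_w.weights, metric)
            rel_train = np.array(
                [labels[i] == RELEVANT for i in train_idx], dtype=np.int64
            )
            predicted = []
            for i in range(len(test_idx)):
                m, cnt = _votes_over_grid(d2[i], rel_train, [min(k, s)])[0]
                predicted.append(RELEVANT if m / cnt > 0.5 else IRRELEVANT)
            size_metrics[s].append(compute_metrics(predicted, truth_labels))

    per_size = {s: _mean_metrics(ms) for s, ms in size_metrics.items()}
    return LearningCurve(
        train_sizes=sizes,
        per_size=per_size,
        test_size=test_size,
        replicates=replicates,
        seed=seed,
        k=k,
    )
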