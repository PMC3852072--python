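"""Training-corpus refinement from manually reviewed classifications.

Every manually inspected abstract is a candidate addition to the training
corpus.  Misclassified items (false positives and false negatives) are
always fed back; of the correctly classified items only a randomly selected
fraction is fed back — per class, so the returned balance mirrors the batch
— because wholesale re-ingestion of easy true positives/negatives can
amplify the bias of an already biased model.  Reviewed labels are ground
truth and always overwrite predictions on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import (
    Corpus,
    CorpusError,
    Document,
    LABELS,
    RELEVANT,
    IRRELEVANT,
    relabel,
)


@dataclass(frozen=True)
class ReviewedItem:
    doc_id: str
    predicted_label: str
    reviewed_label: str

    def __post_init__(self) -> None:
        for lab in (self.predicted_label, self.reviewed_label):
            if lab not in LABELS:
                raise CorpusError(f"unknown label {lab!r} for {self.doc_id}")

    @property
    def is_error(self) -> bool:
        return self.predicted_label != self.reviewed_label


@dataclass(frozen=True)
class ReviewedBatch:
    items: tuple[ReviewedItem, ...]
    review_round: int = 0

    def __post_init__(self) -> None:
        ids = [it.doc_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise CorpusError("reviewed batch contains duplicate doc_ids")


@dataclass(frozen=True)
class FeedbackPolicy:
    """keep_all_errors is fixed true; correct_fraction defaults to 0.25."""

    correct_fraction: float = 0.25
    seed: int = 0
    keep_all_errors: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.correct_fraction <= 1.0:
            raise ValueError("correct_fraction must be in [0, 1]")
        if not self.keep_all_errors:
            raise ValueError("keep_all_errors is fixed TRUE by policy")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_feedback(batch: ReviewedBatch, policy: FeedbackPolicy) -> set[str]:
    """Choose which reviewed doc_ids enter the training corpus.

    All misclassified items are selected.  Within the true positives and,
    independently, within the true negatives, round(fraction x count) items
    are drawn without replacement; the draw is deterministic given the
    policy seed.
    """
    selected = {it.doc_id for it in batch.items if it.is_error}
    rng = np.random.default_rng([policy.seed, batch.review_round])
    for cls in (RELEVANT, IRRELEVANT):
        correct = sorted(
            it.doc_id
            for it in batch.items
            if not it.is_error and it.reviewed_label == cls
        )
        n_take = _round_half_up(policy.correct_fraction * len(correct))
        if n_take:
            chosen = rng.choice(len(correct), size=n_take, replace=False)
            selected.update(correct[i] for i in sorted(chosen.tolist()))
    return selected


def augment_training(
    corpus: Corpus,
    batch: ReviewedBatch,
    selection: set[str],
    documents: Mapping[str, Document],
) -> Corpus:
    """Append selected reviewed documents, labeled with their reviewed label.

    ``documents`` maps doc_id to the full article record (the reviewed batch
    itself carries only ids and labels).  Existing documents and labels are
    preserved; a doc_id collision with the current corpus is an error.
    """
    batch_ids = {it.doc_id for it in batch.items}
    stray = selection - batch_ids
    if stray:
        raise CorpusError(f"selection not in reviewed batch: {sorted(stray)}")
    existing = set(corpus.doc_ids)
    collision = selection & existing
    if collision:
        raise CorpusError(
            f"doc_id(s) already in training corpus: {sorted(collision)}"
        )
    reviewed_label = {it.doc_id: it.reviewed_label for it in batch.items}
    additions = []
    for it in batch.items:  # batch order, deterministic
        if it.doc_id in selection:
            try:
                doc = documents[it.doc_id]
            except KeyError:
                raise CorpusError(f"no document record for {it.doc_id}") from None
            additions.append(relabel(doc, reviewed_label[it.doc_id]))
    return Corpus(
        list(corpus.documents) + additions,
        provenance=f"{corpus.provenance} +round{batch.review_round}"
        f"({len(additions)} docs)".strip(),
    )


@dataclass(frozen=True)
class FeedbackSimulation:
    """Trace of a simulated multi-round curation campaign.

    ``holdout_accuracy[r]`` is the accuracy of a model trained on the corpus
    after ``r`` review rounds, measured on a fixed labeled test corpus
    (element 0 is the initial corpus before any feedback).
    """

    corpus_sizes: tuple[int, ...]
    holdout_accuracy: tuple[float, ...]
    errors_per_round: tuple[int, ...]
    selected_per_round: tuple[int, ...]


def simulate_review_rounds(
    stream: Corpus,
    test: Corpus,
    policy: FeedbackPolicy,
    initial_per_class: int = 13,
    batch_per_class: int = 13,
    n_rounds: int = 5,
    k: int = 6,
    cfg=None,
) -> FeedbackSimulation:
    """Replay the curation workflow on a labeled document stream.

    The first ``initial_per_class`` documents of each class seed the
    training corpus.  Each round classifies the next ``batch_per_class``
    documents per class with a freshly trained model, 'reviews' them against
    their true labels, applies the selective feedback policy and augments
    the corpus.  Model quality is tracked on the fixed ``test`` corpus:
    the corpus grown by feedback is deliberately enriched in hard
    (misclassified) documents, so in-corpus cross-validation would conflate
    model improvement with corpus difficulty.
    """
    from .knn import classify as knn_classify, train as knn_train
    from .evaluation import compute_metrics

    rel = [d for d in stream.documents if d.label == RELEVANT]
    irr = [d for d in stream.documents if d.label == IRRELEVANT]
    need = initial_per_class + batch_per_class * n_rounds
    if len(rel) < need or len(irr) < need:
        raise CorpusError(
            f"stream too small: need {need} documents per class, "
            f"have ({len(rel)}, {len(irr)})"
        )
    test_unlabeled = Corpus(
        [Document(d.doc_id, d.title, d.abstract, d.mesh_terms) for d in test]
    )
    test_truth = [d.label for d in test.documents]

    def holdout_accuracy(corpus: Corpus) -> float:
        model = knn_train(corpus, k=min(k, len(corpus)), cfg=cfg)
        predicted = {
            p.doc_id: p.predicted_label
            for p in knn_classify(model, test_unlabeled)
        }
        return compute_metrics(
            [predicted[d.doc_id] for d in test.documents], test_truth
        ).accuracy

    corpus = Corpus(rel[:initial_per_class] + irr[:initial_per_class],
                    provenance="simulated stream round 0")
    sizes = [len(corpus)]
    accuracies = [holdout_accuracy(corpus)]
    errors = []
    selected_counts = []
    for rnd in range(n_rounds):
        lo = initial_per_class + batch_per_class * rnd
        hi = lo + batch_per_class
        batch_docs = rel[lo:hi] + irr[lo:hi]
        model = knn_train(corpus, k=min(k, len(corpus)), cfg=cfg)
        unlabeled = Corpus(
            [Document(d.doc_id, d.title, d.abstract, d.mesh_terms)
             for d in batch_docs]
        )
        truth = {d.doc_id: d.label for d in batch_docs}
        ranked = knn_classify(model, unlabeled)
        batch = ReviewedBatch(
            tuple(
                ReviewedItem(p.doc_id, p.predicted_label, truth[p.doc_id])
                for p in ranked
            ),
            review_round=rnd + 1,
        )
        selection = select_feedback(batch, policy)
        corpus = augment_training(
            corpus, batch, selection, {d.doc_id: d for d in batch_docs}
        )
        sizes.append(len(corpus))
        accuracies.append(holdout_accuracy(corpus))
        errors.append(sum(it.is_error for it in batch.items))
        selected_counts.append(len(selection))
    return FeedbackSimulation(
        corpus_sizes=tuple(sizes),
        holdout_accuracy=tuple(accuracies),
        errors_per_round=tuple(errors),
        selected_per_round=tuple(selected_counts),
    )


def read_reviews(path, review_round: int = 0) -> ReviewedBatch:
    """Read a review TSV: doc_id <tab> predicted_label <tab> reviewed_label."""
    from pathlib import Path

    items = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    start = 0
    if lines and lines[0].split("\t")[:1] == ["doc_id"]:
        start = 1
    for line_num, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusError(f"review file line {line_num}: expected 3 columns")
        items.append(ReviewedItem(*[p.strip() for p in parts]))
    return ReviewedBatch(tuple(items), review_round=review_round)


def write_reviews(batch: ReviewedBatch, path) -> None:
    from pathlib import Path

    lines = ["doc_id\tpredicted_label\treviewed_label"]
    for it in batch.items:
        lines.append(f"{it.doc_id}\t{it.predicted_label}\t{it.reviewed_label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
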