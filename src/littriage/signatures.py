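"""Class-discriminative term signatures.

For every vocabulary term, the per-document raw counts in relevant abstracts
are compared with those in irrelevant abstracts by a Welch two-sample
t-test; ranking the terms by ascending p-value yields the category
signature — the handful of terms (e.g. "immunotherapi", "epitop", "ctl"
after stemming) that drive the relevant/irrelevant separation.

Raw counts, not Tf-Idf weights, are tested: the signature reports average
term frequencies per class.  No multiple-testing correction enters the
ranking; a Benjamini-Hochberg adjusted column is attached as supplementary
information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .corpus_io import Corpus, CorpusError, RELEVANT, IRRELEVANT
from .preprocess import PreprocessConfig, preprocess_corpus
from .vectorize import DocTermMatrix, build_dtm


@dataclass(frozen=True)
class TermStat:
    term: str
    mean_freq_relevant: float
    mean_freq_irrelevant: float
    t_statistic: float
    p_value: float
    p_adjusted: float  # Benjamini-Hochberg, supplementary


@dataclass(frozen=True)
class Signature:
    stats: tuple[TermStat, ...]  # ascending p-value
    n_top: int
    degenerate_terms: tuple[str, ...]  # zero variance in both classes; excluded

    def __post_init__(self) -> None:
        ps = [s.p_value for s in self.stats]
        if any(a > b for a, b in zip(ps, ps[1:])):
            raise ValueError("signature p-values must be non-decreasing")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(s.term for s in self.stats)


def term_ttests(
    dtm: DocTermMatrix, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-term Welch t-tests of counts, relevant vs irrelevant.

    Returns (t, p, mean_relevant, mean_irrelevant, degenerate_mask); t and p
    are NaN where both class count vectors are constant (degenerate terms).
    """
    rel_mask = np.array([lab == RELEVANT for lab in labels])
    counts = dtm.counts.toarray().astype(float)
    a = counts[rel_mask]
    b = counts[~rel_mask]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise CorpusError("both classes need at least 2 documents for t-tests")
    # near-constant columns trigger a scipy precision warning; degenerate
    # terms are masked out below, so silence it
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    return t, p, a.mean(axis=0), b.mean(axis=0), degenerate


def term_signature(
    corpus: Corpus,
    n_top: int = 10,
    cfg: Optional[PreprocessConfig] = None,
) -> Signature:
    """Top ``n_top`` terms most discriminative between the two classes.

    The DTM is built on the full labeled corpus with raw counts.  Degenerate
    terms (identical constant counts in both classes) are excluded from the
    ranking and listed separately.  Ranking ties on p-value break by larger
    absolute t, then term, for determinism.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    counts = corpus.class_counts()
    if counts[RELEVANT] < 2 or counts[IRRELEVANT] < 2:
        raise CorpusError(
            f"both classes need >= 2 documents for t-tests, got {counts}"
        )
    tokenized = preprocess_corpus(corpus, cfg)
    dtm = build_dtm(tokenized)
    t, p, mean_rel, mean_irr, degenerate = term_ttests(dtm, list(corpus.labels))

    terms = dtm.vocabulary.terms
    usable = np.flatnonzero(~degenerate & np.isfinite(p))
    adjusted = np.full(len(terms), np.nan)
    if usable.size:
        adjusted[usable] = stats.false_discovery_control(p[usable], method="bh")
    order = sorted(
        usable.tolist(), key=lambda j: (p[j], -abs(t[j]), terms[j])
    )
    stats_list = tuple(
        TermStat(
            term=terms[j],
            mean_freq_relevant=float(mean_rel[j]),
            mean_freq_irrelevant=float(mean_irr[j]),
            t_statistic=float(t[j]),
            p_value=float(p[j]),
            p_adjusted=float(adjusted[j]),
        )
        for j in order[:n_top]
    )
    return Signature(
        stats=stats_list,
        n_top=n_top,
        degenerate_terms=tuple(terms[j] for j in np.flatnonzero(degenerate)),
    )


def signature_table(sig: Signature) -> list[dict]:
    """Tabular report rows mirroring the above/below-axis figure layout.

    Relevant-class mean frequencies are presented positive, irrelevant-class
    means negative.
    """
    if not sig.stats:
        raise ValueError("signature is empty")
    return [
        {
            "term": s.term,
            "mean_freq_relevant": s.mean_freq_relevant,
            "mean_freq_irrelevant": -s.mean_freq_irrelevant,
            "t_statistic": s.t_statistic,
            "p_value": s.p_value,
            "p_adjusted": s.p_adjusted,
        }
        for s in sig.stats
    ]


def write_signature(sig: Signature, path) -> None:
    from pathlib import Path

    rows = signature_table(sig)
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(
                row["term"] if c == "term" else repr(row[c]) for c in cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_signature_table(path) -> list[dict]:
    from pathlib import Path

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    cols = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        vals = line.split("\t")
        row = {}
        for c, v in zip(cols, vals):
            row[c] = v if c == "term" else float(v)
        rows.append(row)
    return rows
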