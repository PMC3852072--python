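# Methods

## The triage model

`littriage` treats literature triage as binary text categorization with a
ranked interface. A labeled corpus of abstracts (each document = title +
abstract + MeSH headings) is embedded as length-normalized Tf-Idf vectors;
an unlabeled abstract is scored by the fraction of *relevant* documents
among its k nearest training vectors, and a batch of abstracts is returned
sorted by that score. The assumptions are the usual bag-of-words ones: word
order carries no signal, class membership shifts the marginal frequencies
of individual terms, and a modest labeled corpus (hundreds of documents)
covers the vocabulary that matters.

### Preprocessing

Fixed stage order: lowercase → punctuation-to-space → whitespace
tokenization → optional numeric-token removal → stopword removal → synonym
consolidation → Porter stemming → drop empties.

- Punctuation is replaced by spaces, not deleted in place, so compound
  designators split into their informative parts ("HLA-A*0201" → `hla`,
  `a`, `0201`) instead of fusing into one token.
- `remove_numbers` defaults to **false**: numeric tokens encode HLA
  alleles, CD receptors and similar immunological descriptors.
- The stopword list is the standard 174-word English list used by
  mainstream text-mining toolkits, shipped as a data file and replaceable
  per run. Entries must be lowercase and punctuation-free.
- Synonym consolidation is data-driven: a flat two-column lexicon mapping
  variant → canonical form, applied **before** stemming so the lexicon can
  be written in surface forms. Chained mappings (a canonical form that is
  itself a key) are rejected at load. The default lexicon is empty; no
  thesaurus is bundled, because any fixed choice of canonicalization
  (lemma? first synset member?) would be arbitrary — the interface accepts
  whatever lexicon the curator trusts.
- The Porter stemmer is implemented from the classic rule tables and
  verified against the algorithm's published example pairs; stemming can
  be disabled (`stemmer="none"`), in which case the pipeline is exactly
  idempotent.

### Weighting

Tf-Idf with length-normalized tf and a log2 idf fitted on a reference
corpus: `w(d,t) = n(d,t)/n(d) · log2(N/df(t))`. A term occurring in every
reference document has idf 0 and vanishes; a term absent from the
reference gets weight 0; a document with no in-vocabulary tokens keeps an
all-zero row (flagged downstream, never a crash). The idf and vocabulary
are fitted on the **training corpus only** and frozen into the model, so
transforming one query document is independent of any other — verified by
a batch-equals-one-at-a-time test. Sparsity filtering (dropping terms
absent from more than a threshold fraction of documents) is available but
off by default (threshold 1.0): rare terms are cheap to keep in sparse
storage and occasionally informative.

### Classification and ranking

- **Distance: cosine by default, Euclidean as an option.** Cosine is the
  standard distance for Tf-Idf vectors: it compares term-usage direction
  and ignores the weighted norm. Euclidean (the metric of classic k-NN
  library routines) is kept as a config option but is *not* the default
  because on Tf-Idf vectors it is sensitive to systematic per-class norm
  differences: when one class concentrates more of its token mass in
  idf-downweighted common terms, its vectors are systematically shorter,
  and Euclidean neighborhoods collapse onto the shorter-norm class
  regardless of term overlap. On the synthetic benchmark this manifests as
  sensitivity 1.0 / specificity 0.8 at k = 6 (and a learning curve that
  *deteriorates* with training-set size, because a larger corpus supplies
  ever-shorter-norm rows); cosine gives balanced errors and an improving
  curve. Both metrics are exercised against brute-force oracles in the
  test suite.
- **Neighbor ties.** All training rows whose distance equals the k-th
  smallest are included, and the score is the relevant fraction of the
  expanded set. This makes output independent of training-row order. Tie
  detection uses exact equality of the computed distances; in floating
  point, exact ties arise from documents with identical token profiles,
  which both the implementation and the test oracles compute identically.
  Consequently the score is `m/k` whenever no tie straddles position k.
- **Score tie at 0.5** (even k): predicted label is *irrelevant* — triage
  favors precision of the relevant call, and the ranked list, which is the
  actual user interface, is unaffected.
- **Zero-vector queries** (abstract fully outside the training
  vocabulary) are legitimate, flagged, and scored: under cosine they are
  equidistant from all training rows, so tie expansion yields the global
  relevant fraction (the class prior).
- **k = 6 by default**, the neighbor count a 1–155 cross-validated grid
  selects as accurate on corpora of this scale; with it, a classified
  corpus partitions into seven neighbor-count groups (0–6 relevant
  neighbors) for reporting.

### Evaluation

Cross-validation uses stratified folds (the 155/155 class balance is
preserved within folds), refits vocabulary and idf on each training split,
and averages accuracy/sensitivity/specificity as unweighted means over
folds (folds are near-equal). `best_k` ties resolve to the smallest k —
the cheapest model. Rates with empty denominators are NaN with an explicit
flag, never silently 0. Learning curves hold a class-balanced test set
fixed per replicate and grow class-balanced training sets (default
protocol: 13+13 initial, steps of 26 to 260, test 25+25, 25 replicates
with seed control — replication exposes the fold-to-fold fluctuation a
single curve hides).

### Term signatures

Per-term Welch (unequal-variance) two-sample t-tests compare raw
per-document counts between classes; terms are ranked by ascending
p-value (ties: larger |t|, then term). Raw counts are tested, not Tf-Idf
weights, because the signature reports average term frequencies per
class. Degenerate terms (zero variance in both classes) are excluded and
listed. No multiple-testing correction enters the *ranking*; a
Benjamini–Hochberg adjusted column is attached as clearly supplementary
information. The statistic is computed vectorized via scipy and checked
against a scalar Welch formula in the tests (1e-9).

### Feedback loop

Reviewed batches feed back **all** misclassified items plus
`round(fraction × count)` correctly classified items drawn without
replacement *within* true positives and true negatives separately, so the
class balance of fed-back correct items mirrors the batch. The default
fraction is 0.25 — a documented choice, configurable. Rounding is
half-up (`floor(x + 0.5)`) for platform-independent determinism. Reviewed
labels always overwrite predictions on ingest. `simulate_review_rounds`
replays this workflow on a labeled stream and tracks model quality on a
**fixed held-out test corpus**: the fed-back corpus is deliberately
enriched in hard (misclassified) documents, so cross-validating on the
corpus itself conflates model improvement with corpus difficulty drift —
measured on held-out data the accuracy trend across rounds is positive,
while in-corpus CV can trend down even as the model improves.

## The synthetic corpus generator

The generator emulates the statistics the pipeline exploits, not language:

- independent per-term Poisson counts (no burstiness, no topic
  correlation structure);
- a shared background vocabulary (default 2,000 terms) with **Zipfian**
  rates (exponent 1.1, within the 1.0–1.2 range observed for natural
  text), budgeted so both classes average `doc_length_mean` (120) tokens —
  a handful of common terms appear in nearly every document and are
  idf-suppressed, while the long tail appears in one or a few abstracts;
- `class_vocab_size` (50) private terms per class at rate 0.5, the
  specialized vocabulary each class shares internally;
- eight planted discriminative terms, named after stemmed immunology
  signature terms (`immunotherapi`, `epitop`, `tcell`, `ctl`, …), at 3.0
  occurrences per relevant document vs 0.3 per irrelevant one;
- deterministic rendering with mixed case, injected punctuation and
  interleaved stopwords, so preprocessing is genuinely exercised;
- a `moderate_overlap` preset (500-term background, 10 private terms at
  0.3, four planted terms at 1.0 vs 0.4, 60-token documents) for studies
  of training-set growth, where accuracy must sit below the ceiling for a
  trend to be observable.

What passing tests on this generator do **not** show: robustness to word
burstiness, topical heterogeneity inside the irrelevant class, label
noise in the manual annotations, or vocabulary drift over publication
years — all present in real PubMed corpora and all absent from the count
model by design.

## Problem sizes and numerics

The default test and acceptance workloads use corpora of 310 documents
(155 per class, mirroring a realistic manually assembled training set),
five-fold cross-validation, 1–155 neighbor grids, 25-replicate learning
curves and 25-seed feedback simulations — sizes at which every check runs
in seconds while keeping Monte-Carlo error small. Tf-Idf agreement with
the scalar oracle is exact to 1e-12; t-statistics to 1e-9; neighbor sets
match brute force exactly under the documented tie policy. Signature
tables round-trip through TSV via full-precision `repr`.

## Known limitations

- Bag-of-words only: no n-grams, no named entities, no sentence structure.
- The k-NN model stores the full training matrix; fine at 10³–10⁴
  documents, not designed for 10⁶.
- PubMed XML parsing extracts PMID, title, abstract text and MeSH
  descriptor names (qualifiers are ignored); structured abstracts are
  concatenated in file order.
- The ranked-list interface defers the relevance cutoff to the curator;
  no automatic threshold or calibration is attempted.
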