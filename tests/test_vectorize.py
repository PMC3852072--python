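import math

import numpy as np
import pytest

from littriage import (
    TokenizedDocument,
    Vocabulary,
    build_dtm,
    filter_sparse_terms,
    read_matrix,
    tfidf_transform,
    write_matrix,
)
from littriage.vectorize import VectorizeError, compute_idf


def tok(doc_id, tokens):
    return TokenizedDocument(doc_id=doc_id, tokens=tuple(tokens))


def tfidf_oracle(token_lists, ref_lists=None):
    """Independent scalar-loop Tf-Idf: tf_norm x log2(N/df), dict-of-dicts."""
    if ref_lists is None:
        ref_lists = token_lists
    vocab = sorted({t for doc in token_lists for t in doc})
    n_ref = len(ref_lists)
    weights = []
    for doc in token_lists:
        total = len([t for t in doc if t in vocab])
        row = {}
        for term in vocab:
            count = sum(1 for t in doc if t == term)
            df = sum(1 for ref in ref_lists if term in ref)
            if count and total and df:
                row[term] = (count / total) * math.log2(n_ref / df)
            else:
                row[term] = 0.0
        weights.append(row)
    return vocab, weights


class TestBuildDtm:
    def test_counts_match_hand_example(self):
        dtm = build_dtm([tok("d1", ["a", "b", "a"]), tok("d2", ["b"])])
        assert dtm.vocabulary.terms == ("a", "b")
        assert dtm.counts.toarray().tolist() == [[2, 1], [0, 1]]

    def test_projection_drops_unseen_terms(self):
        vocab = Vocabulary(("a", "b"))
        dtm = build_dtm([tok("q", ["c", "b"])], vocabulary=vocab)
        assert dtm.counts.toarray().tolist() == [[0, 1]]

    def test_empty_input_rejected(self):
        with pytest.raises(VectorizeError):
            build_dtm([])

    def test_vocabulary_is_sorted_union_of_tokens(self, separable_corpus, plain_cfg):
        from littriage import preprocess_corpus

        tokenized = preprocess_corpus(separable_corpus, plain_cfg)
        dtm = build_dtm(tokenized)
        union = sorted({t for d in tokenized for t in d.tokens})
        assert list(dtm.vocabulary.terms) == union

    def test_row_sums_equal_in_vocabulary_token_counts(self):
        docs = [tok("d1", ["x", "y", "x", "z"]), tok("d2", ["y"])]
        dtm = build_dtm(docs)
        assert dtm.row_token_counts().tolist() == [4, 1]


class TestTfidf:
    def test_single_document_all_zero(self):
        w = tfidf_transform(build_dtm([tok("d1", ["a", "b"])]))
        assert w.weights.nnz == 0

    def test_ubiquitous_term_column_zero(self):
        dtm = build_dtm([tok("d1", ["a", "b"]), tok("d2", ["a"])])
        w = tfidf_transform(dtm)
        a_col = w.vocabulary.term_index["a"]
        assert np.all(w.weights.toarray()[:, a_col] == 0)

    def test_two_doc_hand_value(self):
        # counts [[2,1],[1,0]]: weight(doc1, b) = (1/3) * log2(2/1) = 1/3
        dtm = build_dtm([tok("d1", ["a", "a", "b"]), tok("d2", ["a"])])
        w = tfidf_transform(dtm).weights.toarray()
        j = {"a": 0, "b": 1}
        assert w[0, j["b"]] == pytest.approx(1 / 3, abs=1e-15)
        assert w[0, j["a"]] == 0  # a occurs in every document

    def test_matches_scalar_oracle(self):
        docs = [
            ["epitop", "tumor", "tumor", "hla"],
            ["tumor", "surgeri"],
            ["epitop", "epitop", "vaccin", "hla", "hla"],
        ]
        dtm = build_dtm([tok(f"d{i}", d) for i, d in enumerate(docs)])
        w = tfidf_transform(dtm).weights.toarray()
        vocab, expected = tfidf_oracle(docs)
        assert list(dtm.vocabulary.terms) == vocab
        for i, row in enumerate(expected):
            for term, val in row.items():
                j = dtm.vocabulary.term_index[term]
                assert w[i, j] == pytest.approx(val, abs=1e-12)

    def test_zero_token_row_stays_zero(self):
        dtm = build_dtm([tok("d1", ["a"]), tok("d2", [])])
        w = tfidf_transform(dtm).weights.toarray()
        assert np.all(w[1] == 0)

    def test_reference_vocabulary_mismatch_rejected(self):
        dtm1 = build_dtm([tok("d1", ["a"])])
        dtm2 = build_dtm([tok("d1", ["b"])])
        with pytest.raises(VectorizeError):
            tfidf_transform(dtm1, reference=dtm2)

    def test_duplicated_token_multiset_leaves_weights_unchanged(self):
        # tf is length-normalised, so doubling every token of a document
        # changes nothing given a fixed reference
        base = [["a", "b"], ["b", "c"], ["a", "c", "c"]]
        ref = build_dtm([tok(f"d{i}", d) for i, d in enumerate(base)])
        idf = compute_idf(ref)
        single = build_dtm([tok("q", ["a", "c", "c"])], vocabulary=ref.vocabulary)
        doubled = build_dtm([tok("q", ["a", "c", "c"] * 2)], vocabulary=ref.vocabulary)
        w1 = tfidf_transform(single, idf=idf).weights.toarray()
        w2 = tfidf_transform(doubled, idf=idf).weights.toarray()
        np.testing.assert_allclose(w1, w2, atol=1e-15)

    def test_batch_equals_one_at_a_time_with_frozen_reference(self):
        # no information leaks between query documents
        ref = build_dtm([tok("r1", ["a", "b"]), tok("r2", ["b", "c"]), tok("r3", ["c"])])
        idf = compute_idf(ref)
        queries = [["a", "c"], ["b", "b", "d"], []]
        batch = tfidf_transform(
            build_dtm([tok(f"q{i}", q) for i, q in enumerate(queries)],
                      vocabulary=ref.vocabulary),
            idf=idf,
        ).weights.toarray()
        for i, q in enumerate(queries):
            solo = tfidf_transform(
                build_dtm([tok("solo", q)], vocabulary=ref.vocabulary), idf=idf
            ).weights.toarray()
            np.testing.assert_array_equal(batch[i], solo[0])

    def test_stays_sparse(self):
        docs = [tok(f"d{i}", [f"t{i}", "common"]) for i in range(10)]
        dtm = build_dtm(docs)
        w = tfidf_transform(dtm)
        assert w.weights.nnz <= dtm.counts.nnz


class TestSparsityFilter:
    def test_threshold_one_is_identity(self):
        dtm = build_dtm([tok("d1", ["a"]), tok("d2", ["b"])])
        assert filter_sparse_terms(dtm, 1.0) is dtm

    def test_rare_term_removed(self):
        docs = [tok(f"d{i}", ["common"] + (["rare"] if i == 0 else []))
                for i in range(100)]
        filtered = filter_sparse_terms(build_dtm(docs), 0.98)
        assert filtered.vocabulary.terms == ("common",)
        assert filtered.doc_ids == tuple(f"d{i}" for i in range(100))

    def test_matches_per_term_absence_oracle(self):
        rng = np.random.default_rng(3)
        docs = [
            tok(f"d{i}", [f"t{j}" for j in rng.integers(0, 30, size=15)])
            for i in range(40)
        ]
        dtm = build_dtm(docs)
        threshold = 0.9
        filtered = filter_sparse_terms(dtm, threshold)
        expected = [
            term
            for term in dtm.vocabulary.terms
            if 1 - sum(term in d.tokens for d in docs) / 40 <= threshold
        ]
        assert list(filtered.vocabulary.terms) == expected

    def test_all_removed_raises_advice(self):
        dtm = build_dtm([tok(f"d{i}", [f"t{i}"]) for i in range(10)])
        with pytest.raises(VectorizeError, match="raise max_sparsity"):
            filter_sparse_terms(dtm, 0.5)


def test_matrix_market_round_trip(tmp_path):
    docs = [tok("d1", ["a", "b", "a"]), tok("d2", ["b"]), tok("d3", [])]
    dtm = build_dtm(docs)
    path = tmp_path / "m.mtx"
    write_matrix(dtm, path)
    again = read_matrix(path)
    assert again.doc_ids == dtm.doc_ids
    assert again.vocabulary.terms == dtm.vocabulary.terms
    assert (again.counts != dtm.counts).nnz == 0
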