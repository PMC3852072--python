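import numpy as np
import pytest
from scipy.spatial.distance import cdist

from littriage import (
    Corpus,
    Document,
    GeneratorSpec,
    PreprocessConfig,
    bin_by_neighbor_count,
    classify,
    generate,
    load_model,
    save_model,
    train,
)
from littriage.knn import (
    ModelError,
    embed,
    neighbor_votes,
    pairwise_distances,
    score_queries,
)


def brute_force_votes(query_row, training_rows, rel, k):
    """Oracle: dense all-pairs scan with tie expansion at the k-th distance."""
    d = cdist(query_row[None, :], training_rows, metric="sqeuclidean")[0]
    kth = sorted(d)[k - 1]
    members = d <= kth
    return int(rel[members].sum()), int(members.sum())


@pytest.fixture(scope="module")
def small_model(separable_corpus):
    return train(separable_corpus, k=6)


class TestTrain:
    def test_model_holds_all_training_rows(self, separable_corpus, small_model):
        assert small_model.n_training == len(separable_corpus)
        assert len(small_model.training_labels) == len(separable_corpus)

    def test_single_class_corpus_rejected(self):
        docs = [Document(f"d{i}", "t", "some text", (), "relevant") for i in range(4)]
        with pytest.raises(ModelError, match="both classes"):
            train(Corpus(docs), k=1)

    def test_k_larger_than_n_rejected(self, tiny_labeled_corpus):
        with pytest.raises(ModelError):
            train(tiny_labeled_corpus, k=7)

    def test_unlabeled_corpus_rejected(self, tiny_labeled_corpus):
        docs = list(tiny_labeled_corpus.documents) + [Document("u1", "t", "a")]
        with pytest.raises(ModelError, match="fully labeled"):
            train(Corpus(docs), k=1)

    def test_minimal_two_doc_corpus(self):
        docs = [
            Document("r", "", "epitope epitope", (), "relevant"),
            Document("i", "", "surgery surgery", (), "irrelevant"),
        ]
        model = train(Corpus(docs), k=1)
        assert model.k == 1


class TestClassify:
    def test_identical_query_to_relevant_doc_scores_one(self, tiny_labeled_corpus):
        model = train(tiny_labeled_corpus, k=1)
        query = Document("q", tiny_labeled_corpus.documents[0].title,
                         tiny_labeled_corpus.documents[0].abstract,
                         tiny_labeled_corpus.documents[0].mesh_terms)
        ranked = classify(model, Corpus([query]))
        assert ranked.predictions[0].score == 1.0
        assert ranked.predictions[0].predicted_label == "relevant"

    def test_k_equals_n_gives_global_relevant_fraction(self, tiny_labeled_corpus):
        model = train(tiny_labeled_corpus, k=len(tiny_labeled_corpus))
        ranked = classify(model, Corpus([Document("q", "", "epitope")]))
        assert ranked.predictions[0].score == 3 / 6

    def test_score_is_relevant_neighbor_ratio(self, benchmark_spec):
        corpus = generate(GeneratorSpec(n_relevant=40, n_irrelevant=40,
                                        shared_vocab_size=200, seed=5))
        model = train(corpus, k=6)
        queries = Corpus([Document(f"q{i}", d.title, d.abstract, d.mesh_terms)
                          for i, d in enumerate(corpus.documents[:20])])
        for p in classify(model, queries):
            assert p.score == p.relevant_neighbor_count / p.neighbor_count
            assert p.predicted_label == (
                "relevant" if p.score > 0.5 else "irrelevant"
            )

    def test_ranked_list_sorted_score_desc_then_doc_id(self, small_model, separable_corpus):
        queries = Corpus([Document(f"q{i}", d.title, d.abstract)
                          for i, d in enumerate(separable_corpus.documents)])
        ranked = classify(small_model, queries)
        keys = [(-p.score, p.doc_id) for p in ranked]
        assert keys == sorted(keys)

    def test_permutation_invariance(self, small_model, separable_corpus):
        docs = [Document(f"q{i}", d.title, d.abstract)
                for i, d in enumerate(separable_corpus.documents[:20])]
        ranked_fwd = classify(small_model, Corpus(docs))
        ranked_rev = classify(small_model, Corpus(list(reversed(docs))))
        assert ranked_fwd.predictions == ranked_rev.predictions

    def test_determinism_byte_identical(self, small_model, separable_corpus):
        a = classify(small_model, separable_corpus)
        b = classify(small_model, separable_corpus)
        assert a.predictions == b.predictions

    def test_zero_vector_query_flagged_not_crashing(self, small_model):
        ranked = classify(
            small_model, Corpus([Document("q", "zzz unknownterm", "outofvocab")])
        )
        assert ranked.predictions[0].zero_vector
        assert 0.0 <= ranked.predictions[0].score <= 1.0

    def test_self_classification_k1_reproduces_training_labels(self, separable_corpus):
        model = train(separable_corpus, k=1)
        queries = Corpus([
            Document(f"q_{d.doc_id}", d.title, d.abstract, d.mesh_terms)
            for d in separable_corpus.documents
        ])
        ranked = classify(model, queries)
        truth = {f"q_{d.doc_id}": d.label for d in separable_corpus.documents}
        for p in ranked:
            assert p.predicted_label == truth[p.doc_id]


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_neighbor_votes_match_dense_scan(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(20, 120)), int(rng.integers(5, 40))
        import scipy.sparse as sp

        training = sp.random(n, m, density=0.3, random_state=np.random.RandomState(seed), format="csr")
        queries = sp.random(12, m, density=0.3, random_state=np.random.RandomState(seed + 1), format="csr")
        rel = rng.integers(0, 2, size=n).astype(bool)
        k = int(rng.integers(1, min(n, 9)))
        d2 = pairwise_distances(queries, training, metric="euclidean")
        qd = queries.toarray()
        td = training.toarray()
        for i in range(12):
            got = neighbor_votes(d2[i], rel, k)
            want = brute_force_votes(qd[i], td, rel, k)
            assert got == want

    def test_tie_expansion_with_duplicate_training_rows(self):
        # three identical relevant rows tie at the k-th position: the vote
        # includes all of them
        docs = [
            Document("r1", "", "epitope tumor", (), "relevant"),
            Document("r2", "", "epitope tumor", (), "relevant"),
            Document("r3", "", "epitope tumor", (), "relevant"),
            Document("i1", "", "surgery imaging", (), "irrelevant"),
            Document("i2", "", "pharmacokinetics dosing", (), "irrelevant"),
        ]
        model = train(Corpus(docs), k=2)
        ranked = classify(model, Corpus([Document("q", "", "epitope tumor")]))
        p = ranked.predictions[0]
        assert p.neighbor_count == 3
        assert p.relevant_neighbor_count == 3
        assert p.score == 1.0

    @pytest.mark.parametrize("metric", ["cosine", "euclidean"])
    def test_sklearn_cross_check_on_synthetic_corpus(self, metric):
        """Independent check of the whole embed+vote path against
        scikit-learn's KNeighborsClassifier on the same weighted vectors."""
        from sklearn.neighbors import KNeighborsClassifier

        corpus = generate(GeneratorSpec(n_relevant=40, n_irrelevant=40,
                                        shared_vocab_size=300, seed=13))
        holdout = generate(GeneratorSpec(n_relevant=15, n_irrelevant=15,
                                         shared_vocab_size=300, seed=14))
        model = train(corpus, k=5, metric=metric)
        queries = Corpus([Document(f"q{i}", d.title, d.abstract, d.mesh_terms)
                          for i, d in enumerate(holdout.documents)])
        weighted = embed(model, queries)
        preds = {p.doc_id: p for p in score_queries(model, weighted)}

        clf = KNeighborsClassifier(n_neighbors=5, metric=metric)
        clf.fit(model.training_weights.weights.toarray(),
                np.array(model.training_labels))
        proba = clf.predict_proba(weighted.weights.toarray())
        rel_col = list(clf.classes_).index("relevant")
        for i, doc_id in enumerate(weighted.doc_ids):
            assert preds[doc_id].score == pytest.approx(proba[i, rel_col], abs=1e-12)


class TestBinning:
    def test_k6_gives_seven_groups(self, benchmark_spec):
        corpus = generate(GeneratorSpec(n_relevant=30, n_irrelevant=30,
                                        shared_vocab_size=300, seed=2))
        model = train(corpus, k=6)
        ranked = classify(model, corpus)
        hist = bin_by_neighbor_count(ranked, 6)
        assert len(hist) == 7
        assert hist.sum() == len(ranked)

    def test_empty_list_all_zero(self):
        hist = bin_by_neighbor_count([], 6)
        assert hist.tolist() == [0] * 7

    def test_counts_match_brute_tally(self, small_model, separable_corpus):
        ranked = classify(small_model, separable_corpus)
        hist = bin_by_neighbor_count(ranked, small_model.k)
        for m in range(small_model.k + 1):
            expected = sum(
                min(p.relevant_neighbor_count, small_model.k) == m for p in ranked
            )
            assert hist[m] == expected


class TestSerialization:
    def test_round_trip_preserves_predictions(self, small_model, separable_corpus, tmp_path):
        path = tmp_path / "model.json"
        save_model(small_model, path)
        again = load_model(path)
        a = classify(small_model, separable_corpus)
        b = classify(again, separable_corpus)
        assert a.predictions == b.predictions

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bogus.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ModelError):
            load_model(path)
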