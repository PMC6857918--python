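import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.optimize import linear_sum_assignment

from survtopic.dlda import (
    DiscretizedMatrix,
    EncodedCorpus,
    TopicBasis,
    discretize,
    encode_counts,
    fit_discretizer,
    fit_lda,
    heldout_likelihood,
    infer_loadings,
    select_basis,
    stratified_folds,
)
from tests.conftest import make_planted_corpus, make_survival_labels


def _match_correlation(A, B):
    """Best-permutation row correlations between two topic matrices."""
    K = A.shape[0]
    C = np.corrcoef(np.vstack([A, B]))[:K, K:]
    r, c = linear_sum_assignment(-C)
    return C[r, c]


class TestDiscretizer:
    def test_positive_side_min_and_width(self):
        z = np.array([[1.0], [2.0], [3.0], [0.2]])
        edges = fit_discretizer(z, ["g"])
        min_pos, delta_pos, min_neg, delta_neg = edges["g"]
        assert (min_pos, delta_pos) == (1.0, 2.0)
        assert min_neg is None and delta_neg is None  # no value <= -1

    def test_single_nontrivial_value_has_zero_width(self):
        edges = fit_discretizer(np.array([[1.7], [0.0]]), ["g"])
        assert edges["g"][:2] == [1.7, 0.0]

    def test_bin_boundaries_enumerated(self):
        # edges min+=1.0, width 2.0 -> boundaries 1.0, 1.2, ..., 3.0;
        # 2.05 sits in the 6th bin ((2.05-1)/0.2 = 5.25)
        edges = {"g": [1.0, 2.0, None, None]}
        z = np.array([[1.0], [3.0], [2.05], [0.3], [4.2], [1.19999]])
        D = discretize(z, ["g"], edges)
        assert list(D.values[:, 0]) == [1, 10, 6, 0, 10, 1]

    def test_negative_side_mirrors_positive(self):
        z_fit = np.array([[-1.0], [-3.0], [0.0]])
        edges = fit_discretizer(z_fit, ["g"])
        D = discretize(np.array([[-1.0], [-3.0], [-2.05], [-9.0]]), ["g"], edges)
        assert list(D.values[:, 0]) == [-1, -10, -6, -10]

    def test_novel_value_below_training_min_clamps_to_first_bin(self):
        edges = {"g": [1.5, 1.0, None, None]}
        D = discretize(np.array([[1.1]]), ["g"], edges)
        assert D.values[0, 0] == 1

    def test_side_absent_in_training_maps_to_nearest_bin(self):
        edges = {"g": [1.0, 1.0, None, None]}
        D = discretize(np.array([[-2.5]]), ["g"], edges)
        assert D.values[0, 0] == -1

    def test_zero_width_side_maps_to_bin_one(self):
        edges = {"g": [1.7, 0.0, None, None]}
        assert discretize(np.array([[1.7]]), ["g"], edges).values[0, 0] == 1

    def test_missing_edges_error(self):
        with pytest.raises(KeyError):
            discretize(np.array([[0.5]]), ["g"], {})


class TestEncodings:
    def test_direction_aware_encoding_examples(self):
        D = DiscretizedMatrix(np.array([[2], [-3], [0]]), ["g"])
        corpus = encode_counts(D, "enc_b")
        # +2 -> [2, 0]; -3 -> [0, 3]; 0 -> empty document
        assert corpus.vocabulary == ["OVER-g", "UNDER-g"]
        assert corpus.counts.tolist() == [[2, 0], [0, 3], [0, 0]]

    def test_magnitude_encoding_conflates_directions(self):
        D = DiscretizedMatrix(np.array([[4], [-4]]), ["g"])
        corpus = encode_counts(D, "enc_a")
        assert corpus.counts.tolist() == [[4], [4]]

    @settings(derandomize=True, max_examples=50)
    @given(
        hst.lists(
            hst.lists(hst.integers(-10, 10), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_encoding_round_trips(self, rows):
        b = np.array(rows)
        D = DiscretizedMatrix(b, ["g1", "g2", "g3"])
        enc_b = encode_counts(D, "enc_b")
        p = 3
        recon = enc_b.counts[:, :p] - enc_b.counts[:, p:]
        assert np.array_equal(recon, b)
        # at most one direction word per gene per patient
        assert not np.any((enc_b.counts[:, :p] > 0) & (enc_b.counts[:, p:] > 0))
        enc_a = encode_counts(D, "enc_a")
        assert np.array_equal(enc_a.counts, np.abs(b))

    def test_unknown_encoding_rejected(self):
        D = DiscretizedMatrix(np.array([[1]]), ["g"])
        with pytest.raises(ValueError):
            encode_counts(D, "enc_c")


class TestFitLDA:
    def test_single_topic_recovers_pooled_word_frequencies(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=1, seed=0, n_restarts=1)
        pooled = corpus.counts.sum(axis=0) / corpus.counts.sum()
        assert np.allclose(basis.beta_bar[0], pooled, atol=1e-9)

    def test_rows_are_probability_vectors(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=1, n_restarts=1)
        assert np.all(basis.beta_bar >= 0)
        assert np.allclose(basis.beta_bar.sum(axis=1), 1.0, atol=1e-8)

    def test_bound_is_nondecreasing_over_em(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0, n_restarts=1)
        el = np.array(basis.elbo_history)
        assert np.all(np.diff(el) >= -1e-8 * np.abs(el[:-1]))

    def test_two_seeds_recover_same_topics_up_to_permutation(self, planted_corpus):
        corpus, _, _ = planted_corpus
        b1 = fit_lda(corpus, K=3, seed=11)
        b2 = fit_lda(corpus, K=3, seed=99)
        assert _match_correlation(b1.beta_bar, b2.beta_bar).min() > 0.95

    def test_recovers_planted_topics(self, planted_corpus):
        corpus, true_beta, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0)
        assert _match_correlation(basis.beta_bar, true_beta).min() > 0.9

    def test_agrees_with_sklearn_variational_lda(self, planted_corpus):
        # independent implementation of the same model family should find
        # the same planted topic set
        from sklearn.decomposition import LatentDirichletAllocation

        corpus, _, _ = planted_corpus
        mine = fit_lda(corpus, K=3, seed=0)
        sk = LatentDirichletAllocation(
            n_components=3, doc_topic_prior=0.1, learning_method="batch",
            max_iter=100, random_state=0,
        ).fit(corpus.counts)
        sk_beta = sk.components_ / sk.components_.sum(axis=1, keepdims=True)
        assert _match_correlation(mine.beta_bar, sk_beta).min() > 0.9

    def test_empty_corpus_rejected(self):
        corpus = EncodedCorpus("enc_b", ["a", "b"], np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            fit_lda(corpus, K=2)

    def test_more_topics_than_documents_warns(self, caplog):
        import logging

        corpus = EncodedCorpus("enc_b", ["a", "b"], np.array([[3, 1], [1, 2]]))
        with caplog.at_level(logging.WARNING, logger="survtopic"):
            fit_lda(corpus, K=5, seed=0, n_restarts=1, max_em_iter=30)
        assert any("exceeds" in r.message for r in caplog.records)


class TestInferLoadings:
    def test_empty_document_returns_uniform_prior(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0, n_restarts=1)
        theta = infer_loadings(np.zeros((1, len(corpus.vocabulary))), basis)
        assert np.allclose(theta, 1 / 3)

    def test_identical_documents_get_identical_loadings(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0, n_restarts=1)
        doc = corpus.counts[:1]
        t1 = infer_loadings(np.vstack([doc, doc]), basis)
        assert np.array_equal(t1[0], t1[1])

    def test_pure_topic_document_loads_on_matched_topic(self, planted_corpus):
        corpus, true_beta, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0)
        rng = np.random.default_rng(5)
        doc = rng.multinomial(200, true_beta[1])
        theta = infer_loadings(doc, basis)[0]
        match = int(np.argmax(_row_corr(basis.beta_bar, true_beta[1])))
        assert theta[match] > 0.9

    def test_raw_loadings_are_dirichlet_parameters(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0, n_restarts=1)
        gamma = infer_loadings(corpus.counts[:5], basis, normalized=False)
        assert np.all(gamma > 0)
        # total mass = alpha*K + document length
        assert np.allclose(
            gamma.sum(axis=1), basis.alpha * 3 + corpus.counts[:5].sum(axis=1)
        )

    def test_patient_permutation_equivariance(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=3, seed=0, n_restarts=1)
        perm = np.random.default_rng(0).permutation(corpus.counts.shape[0])
        t = infer_loadings(corpus.counts, basis)
        tp = infer_loadings(corpus.counts[perm], basis)
        assert np.allclose(tp, t[perm])

    def test_vocabulary_mismatch_errors(self, planted_corpus):
        corpus, _, _ = planted_corpus
        basis = fit_lda(corpus, K=2, seed=0, n_restarts=1, max_em_iter=30)
        with pytest.raises(ValueError, match="vocabulary"):
            infer_loadings(np.zeros((1, 3)), basis)


def _row_corr(A, b):
    return np.array([np.corrcoef(a, b)[0, 1] for a in A])


class TestHeldoutLikelihood:
    def test_single_word_under_uniform_topics_scores_log_inverse_vocab(self):
        V = 8
        basis = TopicBasis(
            K=2, beta_bar=np.full((2, V), 1 / V), alpha=0.1,
            encoding="enc_b", vocabulary=[f"w{j}" for j in range(V)],
        )
        doc = np.zeros((1, V), dtype=int)
        doc[0, 3] = 1
        corpus = EncodedCorpus("enc_b", basis.vocabulary, doc)
        assert heldout_likelihood(corpus, basis) == pytest.approx(-np.log(V))

    def test_empty_document_scores_zero(self):
        V = 4
        basis = TopicBasis(
            K=2, beta_bar=np.full((2, V), 1 / V), alpha=0.1,
            encoding="enc_b", vocabulary=[f"w{j}" for j in range(V)],
        )
        corpus = EncodedCorpus("enc_b", basis.vocabulary, np.zeros((1, V), dtype=int))
        assert heldout_likelihood(corpus, basis) == 0.0

    def test_true_topic_count_beats_single_topic(self):
        corpus, _, _ = make_planted_corpus(n_docs=250, seed=3)
        train = corpus.subset(np.arange(200))
        test = corpus.subset(np.arange(200, 250))
        l1 = heldout_likelihood(test, fit_lda(train, K=1, seed=0, n_restarts=1))
        l3 = heldout_likelihood(test, fit_lda(train, K=3, seed=0))
        assert l3 > l1


class TestSelectBasis:
    def test_stratified_fold_sizes_differ_by_at_most_one(self):
        labels = make_survival_labels(n=103, seed=0)
        folds = stratified_folds(labels.event, 5, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(103))
        # event counts also balanced
        ev = [labels.event[f].sum() for f in folds]
        assert max(ev) - min(ev) <= 1

    def test_singleton_grid_returns_that_configuration(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(60, 20)) * 1.5
        labels = make_survival_labels(n=60, seed=1)
        clinical = rng.normal(size=(60, 2))
        result, basis = select_basis(
            z, [f"g{j}" for j in range(20)], clinical, labels,
            K_grid=(2,), encodings=("enc_b",), seed=0,
        )
        assert result.encoding == "enc_b"
        assert result.K == 2 and result.K_hat == 2
        assert basis.K == 2 and basis.encoding == "enc_b"
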