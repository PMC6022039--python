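"""From-scratch classifiers, LBG quantization, the discrete HMM, wrapped
learners and recording-level majority labelling."""

import itertools

import numpy as np
import pytest

from anuracall.classifiers import (DiscreteHmmClassifier,
                                   GaussianMaximumLikelihood,
                                   MinimumDistanceClassifier,
                                   forward_log_likelihood, label_recording,
                                   lbg_codebook, make_classifier, quantize)


class TestMinimumDistance:
    def fitted(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [10.0, 10.0]])
        return MinimumDistanceClassifier().fit(X, np.array([1, 1, 2]))

    def test_means_are_class_averages(self):
        clf = self.fitted()
        assert np.allclose(clf.means_, [[1.0, 1.0], [10.0, 10.0]])

    def test_frame_at_mean_gets_that_class(self):
        clf = self.fitted()
        assert clf.predict([[10.0, 10.0]])[0] == 2

    def test_one_dimensional_example(self):
        clf = MinimumDistanceClassifier().fit([[0.0], [10.0]], [1, 2])
        assert clf.predict([[4.0]])[0] == 1

    def test_tie_breaks_to_lowest_class(self):
        clf = MinimumDistanceClassifier().fit([[0.0], [10.0]], [1, 2])
        assert clf.predict([[5.0]])[0] == 1

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            self.fitted().predict([[1.0, 2.0, 3.0]])

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 5))
        y = rng.integers(0, 4, 200)
        clf = MinimumDistanceClassifier().fit(X, y)
        queries = rng.standard_normal((50, 5))
        for q in queries:
            dists = [np.sum((q - clf.means_[j]) ** 2)
                     for j in range(len(clf.classes_))]
            assert clf.predict([q])[0] == clf.classes_[int(np.argmin(dists))]


class TestGaussianMaximumLikelihood:
    def test_separable_gaussians_high_training_accuracy(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal([0, 0], 1, (500, 2)),
                       rng.normal([8, 8], 1, (500, 2))])
        y = np.array(["a"] * 500 + ["b"] * 500)
        clf = GaussianMaximumLikelihood().fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.99

    def test_mean_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal([0, 0], 1, (500, 2)),
                       rng.normal([8, 8], 1, (500, 2))])
        y = np.array(["a"] * 500 + ["b"] * 500)
        clf = GaussianMaximumLikelihood().fit(X, y)
        se = 1 / np.sqrt(500)
        assert np.all(np.abs(clf.means_ - [[0, 0], [8, 8]]) < 3 * se)

    def test_identical_classes_decided_by_prior(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((100, 2))
        X = np.vstack([base[:80], base[:20]])
        y = np.array(["big"] * 80 + ["small"] * 20)
        clf = GaussianMaximumLikelihood().fit(X, y)
        # same mean and covariance: the prior alone decides
        clf.means_[1] = clf.means_[0]
        clf.covariances_[1] = clf.covariances_[0]
        pred = clf.predict(rng.standard_normal((50, 2)))
        assert np.all(pred == "big")

    def test_singular_covariance_is_regularized(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0],
                      [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = GaussianMaximumLikelihood().fit(X, y)
        assert clf.predict([[1.0, 2.0]])[0] == 0


class TestLbg:
    def test_single_codeword_is_global_centroid(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 3))
        codebook, _ = lbg_codebook(X, 1)
        assert np.allclose(codebook[0], X.mean(axis=0))

    def test_recovers_four_planted_clusters(self):
        rng = np.random.default_rng(4)
        centres = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        X = np.vstack([c + 0.5 * rng.standard_normal((50, 2))
                       for c in centres])
        codebook, _ = lbg_codebook(X, 4, seed=0)
        for c in centres:
            d = np.sqrt(np.sum((codebook - c) ** 2, axis=1)).min()
            assert d < 1.0  # within the cluster radius

    def test_distortion_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 4))
        _, history = lbg_codebook(X, 8, seed=0)
        assert np.all(np.diff(history) <= 1e-9)

    def test_rejects_invalid_codebook_sizes(self):
        X = np.random.default_rng(6).standard_normal((20, 2))
        with pytest.raises(ValueError, match="power of two"):
            lbg_codebook(X, 3)
        with pytest.raises(ValueError, match="distinct"):
            lbg_codebook(np.zeros((20, 2)), 4)


def random_hmm(rng, n_states, n_symbols):
    pi = rng.dirichlet(np.ones(n_states))
    a = rng.dirichlet(np.ones(n_states), n_states)
    b = rng.dirichlet(np.ones(n_symbols), n_states)
    return pi, a, b


def sample_hmm(pi, a, b, length, rng):
    state = rng.choice(len(pi), p=pi)
    obs = []
    for _ in range(length):
        obs.append(rng.choice(b.shape[1], p=b[state]))
        state = rng.choice(a.shape[1], p=a[state])
    return np.array(obs)


class TestHmm:
    @pytest.mark.parametrize("n_states,length", [(2, 5), (3, 5), (3, 6)])
    def test_forward_matches_exhaustive_path_sum(self, n_states, length):
        rng = np.random.default_rng(5)
        pi, a, b = random_hmm(rng, n_states, 4)
        obs = rng.integers(0, 4, length)
        ll = forward_log_likelihood(pi, a, b, obs)
        total = 0.0
        for path in itertools.product(range(n_states), repeat=length):
            p = pi[path[0]] * b[path[0], obs[0]]
            for t in range(1, length):
                p *= a[path[t - 1], path[t]] * b[path[t], obs[t]]
            total += p
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_forward_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(6)
        pi, a, b = random_hmm(rng, 3, 5)
        obs = rng.integers(0, 5, 40)
        model = hmmlearn.CategoricalHMM(n_components=3)
        model.startprob_, model.transmat_, model.emissionprob_ = pi, a, b
        assert forward_log_likelihood(pi, a, b, obs) == pytest.approx(
            model.score(obs.reshape(-1, 1)), abs=1e-8)

    def test_single_state_reduces_to_iid_multinomial(self):
        b = np.array([[0.2, 0.3, 0.5]])
        obs = np.array([0, 2, 2, 1])
        ll = forward_log_likelihood(np.array([1.0]), np.array([[1.0]]), b, obs)
        assert ll == pytest.approx(np.sum(np.log(b[0, obs])))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            forward_log_likelihood(np.array([1.0]), np.array([[1.0]]),
                                   np.array([[1.0]]), np.array([], dtype=int))

    def test_recovers_simulated_chain_classes(self):
        rng = np.random.default_rng(7)
        h1 = (np.array([1.0, 0.0]), np.array([[0.9, 0.1], [0.2, 0.8]]),
              np.array([[0.7, 0.2, 0.05, 0.05], [0.05, 0.05, 0.2, 0.7]]))
        h2 = (np.array([0.5, 0.5]), np.array([[0.5, 0.5], [0.5, 0.5]]),
              np.array([[0.1, 0.6, 0.25, 0.05], [0.3, 0.1, 0.1, 0.5]]))

        def seqs(h, n):
            return [sample_hmm(*h, 100, rng).astype(float).reshape(-1, 1)
                    for _ in range(n)]

        train = seqs(h1, 10) + seqs(h2, 10)
        labels = ["h1"] * 10 + ["h2"] * 10
        test = seqs(h1, 20) + seqs(h2, 20)
        truth = np.array(["h1"] * 20 + ["h2"] * 20)
        clf = DiscreteHmmClassifier(n_states=2, codebook_size=4,
                                    seed=0).fit(train, labels)
        assert np.mean(clf.predict(test) == truth) >= 0.95

    def test_quantize_nearest_codeword(self):
        codebook = np.array([[0.0], [1.0], [2.0]])
        assert quantize(np.array([[0.1], [1.6], [0.9]]),
                        codebook).tolist() == [0, 2, 1]


class TestWrappedRegistry:
    SEPARABLE_KINDS = ("MinDis", "MaxLik", "DecTr", "kNN", "SVM", "LogReg",
                       "Neur", "Discr", "Bayes")

    @pytest.mark.parametrize("kind", SEPARABLE_KINDS)
    def test_separable_training_set_fit_perfectly(self, kind):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal([0, 0], 0.3, (40, 2)),
                       rng.normal([6, 6], 0.3, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        clf = make_classifier(kind, seed=0)
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_knn_k1_self_classification(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 3, 30)
        clf = make_classifier("kNN", n_neighbors=1)
        clf.fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    @pytest.mark.parametrize("kind", ["MinDis", "MaxLik", "DecTr", "kNN",
                                      "Bayes"])
    def test_constant_label_training_set(self, kind):
        X = np.random.default_rng(10).standard_normal((20, 2))
        y = np.full(20, 7)
        clf = make_classifier(kind)
        clf.fit(X, y)
        assert np.all(clf.predict(X) == 7)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("Quantum")


class TestLabelRecording:
    def test_unanimous(self):
        assert label_recording([2, 2, 2]) == 2

    def test_majority(self):
        # counts (3, 5, 1): class 2 wins
        assert label_recording([1] * 3 + [2] * 5 + [3]) == 2

    def test_tie_breaks_to_lowest_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert label_recording([1, 1, 2, 2]) == 1
        assert "tie" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            label_recording([])
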