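"""Gaussian MAP, k-NN, RBF-SVM and the back-propagation network."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from oitkit import (
    ClassifierConfig,
    ann_predict,
    ann_should_stop,
    ann_train,
    bdm_fit,
    bdm_predict,
    fit_predict,
    hidden_neuron_count,
    knn_predict,
    svm_predict,
    svm_train,
)
from oitkit.classifiers import MlpModel, _sigmoid


def _three_gaussians(rng, n_per=100, dim=30, sep=0.5, std=0.08):
    # class clouds on the [0, 1] scale the pipeline's normalized
    # features live on (the pinned RBF gamma presumes that scale)
    means = sep * np.eye(dim)[:3]
    x = np.vstack([rng.normal(scale=std, size=(n_per, dim)) + m for m in means])
    y = np.repeat(["a", "b", "c"], n_per)
    return x, y


class TestBdm:
    def test_parameter_recovery_from_known_gaussians(self):
        rng = np.random.default_rng(0)
        n = 10_000
        mu = np.array([[0.0, 0.0], [3.0, -1.0]])
        x = np.vstack([rng.normal(size=(n, 2)) + mu[0], rng.normal(size=(n, 2)) + mu[1]])
        y = np.repeat([0, 1], n)
        model = bdm_fit(x, y)
        se = 1.0 / np.sqrt(n)
        assert np.all(np.abs(model.means - mu) < 3 * se)

    def test_duplicated_point_class_is_regularized(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [0.5, 0.1]])
        y = np.array([0, 0, 1, 1])
        model = bdm_fit(x, y)
        pred = bdm_predict(model, [[1.0, 2.0], [0.2, 0.05]])
        assert np.all(np.isfinite(model.log_priors))
        assert list(pred) == [0, 1]

    def test_shared_spherical_covariance_reduces_to_nearest_mean(self, rng):
        # classes built from one shifted, whitened cloud share an exactly
        # spherical sample covariance, so the MAP rule collapses to
        # Euclidean nearest-mean
        base = rng.normal(size=(60, 4))
        base -= base.mean(axis=0)
        base = base @ np.linalg.inv(np.linalg.cholesky(np.cov(base.T, bias=True))).T
        mus = np.array([[0, 0, 0, 0], [4, 0, 0, 0], [0, 4, 0, 0]], dtype=float)
        x = np.vstack([base + m for m in mus])
        y = np.repeat([0, 1, 2], 60)
        model = bdm_fit(x, y)
        test = rng.normal(size=(50, 4)) * 3
        pred = bdm_predict(model, test)
        nearest = np.argmin(cdist(test, model.means), axis=1)
        np.testing.assert_array_equal(pred, nearest)

    def test_1d_equal_variance_boundary_at_midpoint(self, rng):
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(4, 1, 5000)])[:, None]
        y = np.repeat([0, 1], 5000)
        model = bdm_fit(x, y)
        eps = 0.15
        mid = 0.5 * (model.means[0, 0] + model.means[1, 0])
        assert bdm_predict(model, [[mid - eps]])[0] == 0
        assert bdm_predict(model, [[mid + eps]])[0] == 1

    def test_doubling_prior_shifts_1d_boundary(self):
        # equal variances sigma^2: boundary moves by sigma^2 ln2 / delta-mu
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 4000)
        base = (base - base.mean()) / base.std()  # exact moments
        x = np.concatenate([base, base + 4.0, base + 4.0])[:, None]
        y = np.repeat([0, 1, 1], 4000)  # class 1 has double prior
        model = bdm_fit(x, y)
        shift = np.log(2) / 4.0  # sigma^2 ln2 / (mu2 - mu1)
        eps = 0.02
        assert bdm_predict(model, [[2.0 - shift + eps]])[0] == 1
        assert bdm_predict(model, [[2.0 - shift - eps]])[0] == 0

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            bdm_fit(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestKnn:
    def test_k1_returns_exact_match(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.arange(20)
        assert knn_predict(x, y, x[7][None, :], k=1)[0] == 7

    def test_matches_bruteforce_recount(self, rng):
        x = rng.normal(size=(300, 10))
        y = rng.choice(["a", "b", "c", "d"], size=300)
        queries = rng.normal(size=(100, 10))
        pred = knn_predict(x, y, queries, k=7)
        for q, p in zip(queries, pred):
            d = np.linalg.norm(x - q, axis=1)
            nn = np.argsort(d, kind="stable")[:7]
            labels, counts = np.unique(y[nn], return_counts=True)
            winners = labels[counts == counts.max()]
            if len(winners) == 1:
                assert p == winners[0]
            else:
                assert p in winners

    def test_vote_tie_broken_by_mean_distance(self):
        # k=2: one neighbor of each class; the closer class must win
        x = np.array([[0.0], [1.0]])
        y = np.array(["far", "near"])
        assert knn_predict(x, y, [[0.9]], k=2)[0] == "near"

    def test_k_larger_than_training_set_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict(np.zeros((3, 2)), np.array([0, 1, 0]), np.zeros((1, 2)), k=4)


class TestSvm:
    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(size=(40, 2)), rng.normal(size=(40, 2)) + 6.0])
        y = np.repeat([0, 1], 40)
        model = svm_train(x, y)
        assert np.mean(svm_predict(model, x) == y) == 1.0

    def test_three_classes_give_three_pairwise_machines(self, rng):
        x, y = _three_gaussians(rng, n_per=30, dim=5, sep=4.0)
        model = svm_train(x, y)
        assert model.decision_function(x[:2]).shape == (2, 3)  # K(K-1)/2 = 3

    def test_default_parameters_are_pinned(self):
        cfg = ClassifierConfig()
        assert cfg.C == 40.0 and cfg.gamma == 0.2

    def test_confidence_fusion_agrees_on_well_separated_data(self, rng):
        x, y = _three_gaussians(rng, n_per=40, dim=5, sep=4.0)
        model = svm_train(x, y)
        test = x[::7]
        np.testing.assert_array_equal(
            svm_predict(model, test, fusion="vote"),
            svm_predict(model, test, fusion="confidence"),
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            svm_train(np.zeros((5, 2)), np.zeros(5))


class TestHiddenNeuronCount:
    @pytest.mark.parametrize("K,expected", [(19, 21), (6, 7), (2, 3), (5, 6), (12, 14)])
    def test_values(self, K, expected):
        # round-half-up of 0.5*(log2(2K) + 2K - 1)
        assert hidden_neuron_count(K) == expected

    def test_below_two_classes_rejected(self):
        with pytest.raises(ValueError):
            hidden_neuron_count(1)


class TestAnn:
    def test_stopping_rule_fires_at_epoch_11_on_flat_errors(self):
        errors = []
        for i in range(1, 20):
            errors.append(1.0)
            if ann_should_stop(errors):
                break
        assert len(errors) == 11

    def test_stopping_rule_holds_while_improving(self):
        errors = list(np.linspace(1.0, 0.0, 30))  # improves by >0.01 each epoch
        assert not any(
            ann_should_stop(errors[:i]) for i in range(1, len(errors) + 1)
        )

    def test_same_seed_gives_identical_models(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.choice([0, 1], size=40)
        cfg = ClassifierConfig(seed=5, max_epochs=15)
        m1, m2 = ann_train(x, y, cfg), ann_train(x, y, cfg)
        np.testing.assert_array_equal(m1.w_hidden, m2.w_hidden)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)
        assert m1.epoch_errors == m2.epoch_errors

    def test_learns_margin_separated_toy(self, rng):
        x = np.vstack([rng.normal(size=(60, 2)), rng.normal(size=(60, 2)) + 4.0])
        y = np.repeat([0, 1], 60)
        model = ann_train(x, y, ClassifierConfig(seed=0, max_epochs=200))
        assert np.mean(ann_predict(model, x) == y) >= 0.95

    def test_predict_matches_manual_forward_pass(self):
        # 2 inputs -> 2 hidden -> 2 outputs with hand-set weights
        w1 = np.array([[0.1, -0.2, 0.05], [0.3, 0.1, -0.1]])
        w2 = np.array([[0.2, -0.4, 0.0], [-0.1, 0.5, 0.2]])
        model = MlpModel(classes=np.array(["p", "q"]), w_hidden=w1, w_out=w2)
        x = np.array([[0.7, -1.2]])
        h = _sigmoid(w1 @ np.append(x[0], 1.0))
        o = _sigmoid(w2 @ np.append(h, 1.0))
        expected = "p" if o[0] >= o[1] else "q"
        assert ann_predict(model, x)[0] == expected

    def test_outputs_bounded_by_sigmoid(self, rng):
        x = rng.normal(size=(30, 2))
        y = rng.choice([0, 1], size=30)
        model = ann_train(x, y, ClassifierConfig(seed=1, max_epochs=12))
        m = model.w_hidden.shape[1] - 1
        h = _sigmoid(x @ model.w_hidden[:, :m].T + model.w_hidden[:, m])
        o = _sigmoid(h @ model.w_out[:, :-1].T + model.w_out[:, -1])
        assert np.all((o > 0) & (o < 1))


class TestDecisionMachinery:
    def test_all_four_classifiers_separate_easy_classes(self, rng):
        x, y = _three_gaussians(rng)
        test_idx = rng.permutation(300)[:60]
        train_mask = np.ones(300, dtype=bool)
        train_mask[test_idx] = False
        cfg = ClassifierConfig(seed=0, max_epochs=100)
        for name in ("bdm", "knn", "svm", "ann"):
            pred = fit_predict(name, x[train_mask], y[train_mask], x[test_idx], cfg)
            assert np.mean(pred == y[test_idx]) >= 0.90, name

    def test_label_shuffle_reduces_to_chance(self, rng):
        x, y = _three_gaussians(rng)
        y_shuffled = rng.permutation(y)
        test_idx = rng.permutation(300)[:100]
        train_mask = np.ones(300, dtype=bool)
        train_mask[test_idx] = False
        pred = knn_predict(x[train_mask], y_shuffled[train_mask], x[test_idx], k=7)
        acc = np.mean(pred == y_shuffled[test_idx])
        se = np.sqrt((1 / 3) * (2 / 3) / 100)
        assert abs(acc - 1 / 3) < 3 * se
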