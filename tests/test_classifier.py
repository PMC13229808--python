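"""Loss components, augmentation, MLP geometry, and training behavior."""

import math

import numpy as np
import pytest
from scipy.special import log_softmax
from sklearn.metrics import f1_score, log_loss, recall_score

from nephrotext.classifier import (FusionMLPClassifier, MLPHeadClassifier,
                                   TrainConfig, augment, build_mlp, class_weights,
                                   count_parameters, smooth_labels, train,
                                   weighted_smoothed_ce)
from nephrotext.errors import ConfigError, ShapeError, TrainingError


class TestClassWeights:
    def test_inverse_frequency_example(self):
        np.testing.assert_allclose(class_weights([10, 30], epsilon=1e-12),
                                   [1.5, 0.5], atol=1e-9)

    def test_equal_counts_give_unit_weights(self):
        np.testing.assert_allclose(class_weights([25, 25, 25]), [1, 1, 1])
        np.testing.assert_allclose(class_weights([1, 1, 1], epsilon=0.5), [1, 1, 1])

    @pytest.mark.parametrize("counts", [[3, 17], [1, 5, 100], [7, 7, 2, 50]])
    def test_unit_mean_after_normalization(self, counts):
        assert class_weights(counts).mean() == pytest.approx(1.0, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ConfigError):
            class_weights([10, 0])


class TestSmoothLabels:
    def test_alpha_zero_is_identity(self):
        y = np.eye(4)[2]
        np.testing.assert_array_equal(smooth_labels(y, 0.0), y)

    def test_three_class_example(self):
        out = smooth_labels(np.array([1.0, 0.0, 0.0]), 0.1)
        np.testing.assert_allclose(out, [1 - 0.1 + 0.1 / 3, 0.1 / 3, 0.1 / 3])
        assert out[0] == pytest.approx(0.93333333, abs=1e-6)

    @pytest.mark.parametrize("alpha", np.linspace(0.0, 0.99, 12))
    @pytest.mark.parametrize("C", [2, 3, 5])
    def test_distribution_for_all_alpha(self, alpha, C):
        out = smooth_labels(np.eye(C), alpha)
        np.testing.assert_allclose(out.sum(axis=1), np.ones(C), atol=1e-12)
        assert np.all(out >= 0)

    def test_non_one_hot_rejected(self):
        with pytest.raises(ShapeError):
            smooth_labels(np.array([0.5, 0.5]), 0.1)


class TestWeightedSmoothedCE:
    def test_uniform_logits_give_log_C(self):
        for C in (2, 3, 7):
            logits = np.zeros((4, C))
            labels = np.arange(4) % C
            assert weighted_smoothed_ce(logits, labels) == pytest.approx(math.log(C))

    def test_linear_in_weight(self, rng):
        logits = rng.standard_normal((1, 3))
        labels = np.array([1])
        l1 = weighted_smoothed_ce(logits, labels, np.array([1.0, 1.0, 1.0]), 0.1)
        l2 = weighted_smoothed_ce(logits, labels, np.array([1.0, 2.0, 1.0]), 0.1)
        assert l2 == pytest.approx(2 * l1)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n, C = int(rng.integers(1, 8)), int(rng.integers(2, 5))
            logits = rng.standard_normal((n, C)) * 3
            labels = rng.integers(C, size=n)
            w = rng.uniform(0.2, 3.0, size=C)
            alpha = float(rng.uniform(0, 0.5))
            # independent scalar-loop oracle
            total = 0.0
            for i in range(n):
                logp = log_softmax(logits[i])
                for k in range(C):
                    y_ls = (1 - alpha) * (1.0 if k == labels[i] else 0.0) + alpha / C
                    total -= w[labels[i]] * y_ls * logp[k]
            oracle = total / n
            ours = weighted_smoothed_ce(logits, labels, w, alpha)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_reduces_to_plain_cross_entropy(self, rng):
        logits = rng.standard_normal((20, 3))
        labels = rng.integers(3, size=20)
        probs = np.exp(log_softmax(logits, axis=1))
        reference = log_loss(labels, probs, labels=[0, 1, 2])
        assert weighted_smoothed_ce(logits, labels, None, 0.0) == pytest.approx(
            reference, abs=1e-6)

    def test_shift_invariance(self, rng):
        logits = rng.standard_normal((10, 4))
        labels = rng.integers(4, size=10)
        shifted = logits + rng.standard_normal((10, 1)) * 50
        a = weighted_smoothed_ce(logits, labels, alpha=0.1)
        b = weighted_smoothed_ce(shifted, labels, alpha=0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_nonnegative_at_alpha_zero(self, rng):
        logits = rng.standard_normal((30, 3))
        labels = rng.integers(3, size=30)
        assert weighted_smoothed_ce(logits, labels) >= 0

    def test_nan_logits_rejected(self):
        logits = np.array([[np.nan, 0.0]])
        with pytest.raises(TrainingError):
            weighted_smoothed_ce(logits, np.array([0]))


class TestAugment:
    def test_zero_copies_is_identity(self, rng):
        X = rng.standard_normal((5, 3))
        y = np.arange(5)
        Xa, ya = augment(X, y, 0, 0.5, seed=0)
        np.testing.assert_array_equal(Xa, X)
        np.testing.assert_array_equal(ya, y)

    def test_copy_count_arithmetic(self, rng):
        X = rng.standard_normal((32, 4))
        y = np.zeros(32, dtype=int)
        Xa, ya = augment(X, y, 20, 0.1, seed=0)
        assert Xa.shape[0] == 32 + 640 and len(ya) == 672

    def test_zero_noise_copies_equal_originals(self, rng):
        X = rng.standard_normal((6, 3))
        Xa, _ = augment(X, np.zeros(6), 2, 0.0, seed=0)
        np.testing.assert_array_equal(Xa[6:12], X)
        np.testing.assert_array_equal(Xa[12:18], X)

    def test_original_block_preserved_and_labels_carried(self, rng):
        X = rng.standard_normal((4, 2))
        y = np.array([0, 1, 1, 0])
        Xa, ya = augment(X, y, 3, 0.2, seed=1)
        np.testing.assert_array_equal(Xa[:4], X)
        np.testing.assert_array_equal(ya, np.tile(y, 4))

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((4, 2))
        a, _ = augment(X, np.zeros(4), 2, 0.3, seed=9)
        b, _ = augment(X, np.zeros(4), 2, 0.3, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_training_fold_sd_override(self, rng):
        X = rng.standard_normal((4, 2))
        Xa, _ = augment(X, np.zeros(4), 1, 1.0, seed=0, feature_sd=np.zeros(2))
        np.testing.assert_array_equal(Xa[4:], X)


class TestArchitecture:
    def test_head_parameter_count(self):
        mlp = build_mlp(4196, 1024, 2)
        assert mlp.n_parameters == 4_297_728 + 2_050

    def test_full_stack_parameter_count_near_reference(self):
        total = count_parameters(d_model=4096, proj_dim=1024, hidden_dim=1024,
                                 n_classes=2)
        # 10 projections + gamma + MLP head; reference total ~46.5 M
        assert total == 10 * (4096 * 1024 + 1024) + 1 + 4_299_778
        assert 46e6 < total < 47e6

    def test_degenerate_hidden_dim_valid(self):
        mlp = build_mlp(10, 1, 2)
        z, _ = mlp.forward(np.zeros((3, 10)))
        assert z.shape == (3, 2)

    def test_fitted_estimator_reports_parameter_count(self, rng):
        X = rng.standard_normal((20, 11 * 4))
        y = np.arange(20) % 2
        clf = FusionMLPClassifier(proj_dim=6, hidden_dim=5, epochs=2,
                                  augment_copies=0, random_state=0).fit(X, y)
        expected = count_parameters(d_model=4, proj_dim=6, hidden_dim=5, n_classes=2)
        assert clf.n_parameters_ == expected


class TestTraining:
    def _separable(self, rng, n=40):
        y = np.arange(n) % 2
        X = rng.standard_normal((n, 8)) * 0.1 + np.where(y[:, None] == 1, 3.0, -3.0)
        return X, y

    def test_separable_task_reaches_perfect_training_f1(self, rng):
        X, y = self._separable(rng)
        cfg = TrainConfig(hidden_dim=32, learning_rate=1e-2, epochs=100,
                          augment_copies=0, seed=0)
        model, history = train(X, y, cfg)
        assert f1_score(y, model.predict(X)) == 1.0
        assert len(history) == 100 and np.isfinite(history).all()
        assert history[-1] < history[0]

    def test_same_seed_identical_history(self, rng):
        X, y = self._separable(rng)
        cfg = TrainConfig(hidden_dim=16, epochs=10, augment_copies=2, seed=4)
        _, h1 = train(X, y, cfg)
        _, h2 = train(X, y, cfg)
        assert h1 == h2

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigError):
            train(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))

    def test_class_weighting_helps_minority_recall(self, rng):
        """Averaged over seeds, inverse-frequency weights raise minority recall."""
        rec_w, rec_u = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n_maj, n_min = 60, 8
            y = np.array([0] * n_maj + [1] * n_min)
            X = r.standard_normal((n_maj + n_min, 6)) + np.where(
                y[:, None] == 1, 1.2, -0.2)
            Xte = r.standard_normal((40, 6)) + np.where(
                (np.arange(40) % 2 == 1)[:, None], 1.2, -0.2)
            yte = np.arange(40) % 2
            common = dict(hidden_dim=16, learning_rate=1e-3, epochs=60,
                          augment_copies=0, dropout=0.2, random_state=seed)
            w = MLPHeadClassifier(class_weighting=True, **common).fit(X, y)
            u = MLPHeadClassifier(class_weighting=False, **common).fit(X, y)
            rec_w.append(recall_score(yte, w.predict(Xte)))
            rec_u.append(recall_score(yte, u.predict(Xte)))
        assert np.mean(rec_w) >= np.mean(rec_u)

    def test_fusion_classifier_gradients_match_finite_differences(self, rng):
        D, n = 5, 6
        clf = FusionMLPClassifier(proj_dim=4, hidden_dim=6, epochs=1,
                                  augment_copies=0, dropout=0.0, random_state=0)
        X = rng.standard_normal((n, 11 * D))
        y = np.array([0, 1, 0, 1, 1, 0])
        clf.fit(X, y)
        y_idx = np.searchsorted(clf.classes_, y)
        _, grads, _ = clf._step(X, y_idx, None)
        params = [clf.W_, clf.b_, clf.gamma_] + clf.mlp_.params()
        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 10)):
                old = flat[idx]
                flat[idx] = old + eps
                lp, _, _ = clf._step(X, y_idx, None)
                flat[idx] = old - eps
                lm, _, _ = clf._step(X, y_idx, None)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(num, abs=1e-6)

    def test_fusion_classifier_input_width_validated(self, rng):
        clf = FusionMLPClassifier(proj_dim=4, hidden_dim=4, epochs=1,
                                  augment_copies=0, random_state=0)
        with pytest.raises(ShapeError):
            clf.fit(rng.standard_normal((10, 43)), np.arange(10) % 2)

    def test_sklearn_param_round_trip(self):
        clf = FusionMLPClassifier(proj_dim=7, epochs=5)
        assert FusionMLPClassifier(**clf.get_params()).get_params() == clf.get_params()
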