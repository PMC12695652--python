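"""Probing and fine-tuning heads, and the evaluation metrics."""

import numpy as np
import pytest

from nichelm.heads import (
    CompositionProbe,
    FineTuneConfig,
    LinearClassifier,
    ProbeConfig,
    evaluate,
    fine_tune,
    predict_labels,
    train_composition_probe,
    train_density_probe,
    train_linear_classifier,
    train_multitask_mlp,
)


def _blobs(rng, n_per=150, d=16, sep=4.0):
    X = np.concatenate([
        rng.normal(0, 1, (n_per, d)),
        rng.normal(sep / np.sqrt(d), 1, (n_per, d)),
    ])
    y = np.array(["neg"] * n_per + ["pos"] * n_per)
    idx = rng.permutation(2 * n_per)
    return X[idx], y[idx]


class TestClassifier:
    def test_separable_classes_learned(self):
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X, y = _blobs(rng)
            clf = train_linear_classifier(X[:200], y[:200], ProbeConfig(epochs=20, seed=seed))
            pred = predict_labels(clf, X[200:])
            accs.append((pred.labels == y[200:]).mean())
        assert np.mean(accs) > 0.95

    def test_shuffled_labels_give_chance_f1(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng)
        y_shuffled = rng.permutation(y)
        clf = train_linear_classifier(X[:200], y_shuffled[:200], ProbeConfig(epochs=20, seed=0))
        pred = predict_labels(clf, X[200:])
        f1 = evaluate(pred.labels, y_shuffled[200:], task="label")
        assert abs(f1 - 0.5) < 0.15  # two classes: chance macro-F1 ~ 0.5

    def test_training_deterministic(self):
        rng = np.random.default_rng(1)
        X, y = _blobs(rng)
        a = train_linear_classifier(X, y, ProbeConfig(epochs=3, seed=7))
        b = train_linear_classifier(X, y, ProbeConfig(epochs=3, seed=7))
        assert np.array_equal(a.params["W"], b.params["W"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(np.ones((5, 2)), ["a"] * 5)


class TestPredictLabels:
    def _fixed_classifier(self, W, b):
        clf = LinearClassifier(W.shape[0], classes=tuple(range(W.shape[1])), seed=0)
        clf.params["W"] = W
        clf.params["b"] = b
        return clf

    def test_symmetric_tie_breaks_to_lowest_class(self):
        clf = self._fixed_classifier(np.zeros((2, 2)), np.zeros(2))
        pred = predict_labels(clf, np.array([[1.0, 1.0]]))
        assert pred.labels[0] == 0
        assert pred.certainty[0] == pytest.approx(0.5)

    def test_softmax_certainty(self):
        # logits (2, 0) for input [1]: certainty e^2 / (1 + e^2) ~ 0.881
        clf = self._fixed_classifier(np.array([[2.0, 0.0]]), np.zeros(2))
        pred = predict_labels(clf, np.array([[1.0]]))
        assert pred.certainty[0] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-6)

    def test_logit_shift_invariance(self):
        clf = self._fixed_classifier(np.array([[2.0, 0.0]]), np.zeros(2))
        base = predict_labels(clf, np.array([[1.0]]))
        clf.params["b"] = np.array([5.0, 5.0])
        shifted = predict_labels(clf, np.array([[1.0]]))
        assert base.labels[0] == shifted.labels[0]
        assert base.certainty[0] == pytest.approx(shifted.certainty[0])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        clf = self._fixed_classifier(rng.normal(size=(4, 3)), rng.normal(size=3))
        pred = predict_labels(clf, rng.normal(size=(10, 4)))
        assert np.allclose(pred.probabilities.sum(axis=1), 1.0)
        rows = np.arange(10)
        assert np.allclose(
            pred.certainty, pred.probabilities[rows, pred.probabilities.argmax(axis=1)]
        )


class TestCompositionProbe:
    def test_predictions_always_row_stochastic(self):
        rng = np.random.default_rng(0)
        probe = CompositionProbe(8, categories=("a", "b", "c"), seed=0)
        pred = probe.predict(rng.normal(0, 100, size=(20, 8)))
        assert np.allclose(pred.sum(axis=1), 1.0)

    def test_constant_targets_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 6))
        target = np.array([0.6, 0.3, 0.1])
        T = np.tile(target, (300, 1))
        probe = train_composition_probe(X, T, ProbeConfig(epochs=2000, seed=0))
        assert np.allclose(probe.predict(X), target, atol=0.03)

    def test_realizable_linear_softmax_target_recovered(self):
        maes = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 8))
            W = rng.normal(size=(8, 4))
            Z = X @ W
            T = np.exp(Z) / np.exp(Z).sum(axis=1, keepdims=True)
            probe = train_composition_probe(
                X[:400], T[:400], ProbeConfig(epochs=2500, seed=seed)
            )
            maes.append(evaluate(probe.predict(X[400:]), T[400:], task="composition"))
        assert np.mean(maes) < 0.05

    def test_non_stochastic_targets_rejected(self):
        with pytest.raises(ValueError):
            train_composition_probe(np.ones((4, 3)), np.ones((4, 2)))


class TestDensityProbe:
    def test_realizable_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 10))
        w = rng.normal(size=10)
        y = X @ w + 3.0
        probe = train_density_probe(X[:300], y[:300], ProbeConfig(epochs=5000, seed=0))
        assert evaluate(probe.predict(X[300:]), y[300:], task="density") > 0.99

    def test_uninformative_embeddings_give_nonpositive_r2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 10))
        y = rng.poisson(20.0, size=400).astype(float)  # independent of X
        probe = train_density_probe(X[:300], y[:300], ProbeConfig(epochs=50, seed=0))
        assert evaluate(probe.predict(X[300:]), y[300:], task="density") <= 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(100, 5)), rng.normal(size=100)
        a = train_density_probe(X, y, ProbeConfig(epochs=5, seed=3))
        b = train_density_probe(X, y, ProbeConfig(epochs=5, seed=3))
        assert np.array_equal(a.params["W"], b.params["W"])

    def test_constant_targets_rejected(self):
        with pytest.raises(ValueError):
            train_density_probe(np.ones((5, 2)), np.ones(5))


class TestMultitaskMLP:
    def _targets(self, rng, n, l):
        Z = rng.normal(size=(n, l))
        return np.exp(Z) / np.exp(Z).sum(axis=1, keepdims=True)

    def test_loss_equals_hand_averaged_per_head_mse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        targets = {s: self._targets(rng, 50, 3) for s in (10, 20, 50, 100)}
        mlp = train_multitask_mlp(X, targets, ProbeConfig(epochs=1, seed=0))
        preds = mlp.predict(X)
        expected = np.mean([((preds[s] - targets[s]) ** 2).mean() for s in targets])
        assert mlp.loss(X, targets) == pytest.approx(expected, abs=1e-12)

    def test_identical_targets_give_equal_per_head_losses(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 6))
        shared = self._targets(rng, 200, 3)
        targets = {s: shared for s in (10, 20)}
        mlp = train_multitask_mlp(X, targets, ProbeConfig(epochs=100, seed=0))
        preds = mlp.predict(X)
        losses = [((preds[s] - shared) ** 2).mean() for s in (10, 20)]
        assert losses[0] == pytest.approx(losses[1], rel=0.2)

    def test_single_size_predictions_row_stochastic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        mlp = train_multitask_mlp(X, {10: self._targets(rng, 40, 4)}, ProbeConfig(seed=0))
        assert np.allclose(mlp.predict(X)[10].sum(axis=1), 1.0)

    def test_mismatched_cell_sets_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            train_multitask_mlp(
                rng.normal(size=(10, 4)),
                {10: self._targets(rng, 10, 3), 20: self._targets(rng, 8, 3)},
            )


class TestFineTune:
    def test_zero_steps_is_noop(self, model_small, batch_small):
        sub = batch_small.subset(np.arange(5))  # < one optimizer step of 90 cells
        labels = batch_small.obs["niche_label"].to_numpy()[:5]
        clf = LinearClassifier(model_small.config.d_model, classes=("a", "b"), seed=0)
        before = {k: v.copy() for k, v in model_small.params.items()}
        fine_tune(model_small, clf, sub, np.where(labels == labels[0], "a", "b"))
        assert all(np.array_equal(before[k], model_small.params[k]) for k in before)

    def test_deterministic(self, batch_small, vocab_small):
        from nichelm.embedding import extract_embeddings
        from nichelm.model import EncoderConfig, build_model

        labels = batch_small.obs["niche_label"].to_numpy()[:120]
        sub = batch_small.subset(np.arange(120))

        def run():
            cfg = EncoderConfig(
                vocab_size=vocab_small.size, n_layers=1, n_heads=2,
                d_model=16, d_ffn=32, max_len=128,
            )
            model = build_model(cfg, seed=0)
            emb = extract_embeddings(model, sub)
            clf = train_linear_classifier(emb, labels, ProbeConfig(seed=0))
            fine_tune(model, clf, sub, labels, FineTuneConfig(seed=0, grad_accumulation=2))
            return model

        a, b = run(), run()
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


class TestEvaluate:
    def test_perfect_predictions(self):
        assert evaluate(["a", "b"], ["a", "b"], task="label") == 1.0
        assert evaluate(np.eye(2), np.eye(2), task="composition") == 0.0
        assert evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], task="density") == 1.0

    def test_hand_computed_macro_f1(self):
        """Confusion {A: 2 correct; B: 1 correct, 1 predicted as A}:
        F1_A = 0.8, F1_B = 2/3, macro = 0.733..."""
        truth = ["A", "A", "B", "B"]
        pred = ["A", "A", "B", "A"]
        assert evaluate(pred, truth, task="label") == pytest.approx((0.8 + 2 / 3) / 2)

    def test_constant_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert evaluate(np.full(4, y.mean()), y, task="density") == pytest.approx(0.0)

    def test_classes_absent_from_both_sides_excluded(self):
        # only classes A and B occur; a hypothetical class C does not drag
        # the macro average down
        assert evaluate(["A", "B"], ["A", "B"], task="label") == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [], task="label")
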