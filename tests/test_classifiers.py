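"""Weighted cross-entropy objective, balanced sampling, and training."""

import numpy as np
import pytest

from lesionmgmt.classifiers import (
    ClassWeights,
    ModelParameters,
    TrainingConfig,
    compute_class_weights,
    multi_task_loss,
    one_hot,
    predict_proba,
    sample_balanced_minibatch,
    train_model,
    weighted_cross_entropy,
)
from lesionmgmt.cohort import GeneratorConfig, design_matrix, generate_exact_cohort


class TestClassWeights:
    def test_balanced_classes_get_unit_weights(self):
        w = compute_class_weights(np.array([0] * 10 + [1] * 10), 2)
        np.testing.assert_allclose(w.weights, [1.0, 1.0])

    def test_inverse_frequency_on_management_totals(self):
        # cohort totals 110 NONE / 296 CLNC / 605 EXC
        labels = np.repeat([0, 1, 2], [110, 296, 605])
        w = compute_class_weights(labels, 3)
        np.testing.assert_allclose(w.weights, [3.0636, 1.1385, 0.5570], atol=1e-4)
        # count-weighted mean weight is 1: weighting rescales, not inflates
        counts = np.array([110, 296, 605])
        assert (counts * w.weights).sum() / counts.sum() == pytest.approx(1.0)

    def test_absent_class_is_an_error(self):
        with pytest.raises(ValueError):
            compute_class_weights(np.zeros(5, dtype=int), 2)
        with pytest.raises(ValueError):
            compute_class_weights(np.array([], dtype=int), 2)


class TestWeightedCrossEntropy:
    unit2 = ClassWeights(np.ones(2))

    def test_perfect_prediction_has_zero_loss(self):
        p = np.array([[1.0, 0.0, 0.0]])
        y = np.array([[1.0, 0.0, 0.0]])
        assert weighted_cross_entropy(p, y, ClassWeights(np.ones(3))) == pytest.approx(0.0)

    def test_half_confidence_costs_ln2(self):
        loss = weighted_cross_entropy(
            np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]), self.unit2
        )
        assert loss == pytest.approx(np.log(2), abs=1e-6)

    def test_two_sample_weighted_average(self):
        p = np.array([[0.5, 0.5], [0.75, 0.25]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = weighted_cross_entropy(p, y, ClassWeights(np.array([2.0, 1.0])))
        assert loss == pytest.approx((2 * np.log(2) + np.log(4)) / 2, abs=1e-6)

    def test_rejects_unnormalized_rows_and_shape_mismatch(self):
        y = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.array([[0.7, 0.7]]), y, self.unit2)
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.array([[0.5, 0.25, 0.25]]), y, self.unit2)

    def test_unit_weights_reduce_to_plain_mean_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(4), size=30)
        labels = rng.integers(0, 4, size=30)
        y = one_hot(labels, 4)
        ours = weighted_cross_entropy(probs, y, ClassWeights(np.ones(4)))
        plain = -np.mean(np.log(probs[np.arange(30), labels]))
        assert ours == pytest.approx(plain, rel=1e-12)

    def test_gradient_matches_central_finite_differences(self, rng):
        """Analytic d(loss)/d(logits) = w_y (p - y)/B against numerics."""
        B, K = 6, 3
        logits = rng.normal(size=(B, K))
        labels = rng.integers(0, K, size=B)
        y = one_hot(labels, K)
        w = ClassWeights(rng.uniform(0.5, 3.0, size=K))

        def loss_of(z):
            e = np.exp(z - z.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            return weighted_cross_entropy(p, y, w)

        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        analytic = w.weights[labels][:, None] * (p - y) / B
        eps = 1e-6
        for i in range(B):
            for j in range(K):
                zp, zm = logits.copy(), logits.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (loss_of(zp) - loss_of(zm)) / (2 * eps)
                assert num == pytest.approx(analytic[i, j], rel=1e-5, abs=1e-8)


class TestMultiTaskLoss:
    def test_sums_per_task_losses(self, rng):
        tasks = {}
        targets = {}
        weights = {}
        per_task = []
        for t in ("diagnosis", "management", "criterion_1"):
            k = 3
            probs = rng.dirichlet(np.ones(k), size=10)
            labels = rng.integers(0, k, size=10)
            tasks[t] = probs
            targets[t] = one_hot(labels, k)
            weights[t] = ClassWeights(np.ones(k))
            per_task.append(weighted_cross_entropy(probs, targets[t], weights[t]))
        assert multi_task_loss(tasks, targets, weights) == pytest.approx(sum(per_task))

    def test_two_half_confident_tasks_cost_two_ln2(self):
        p = {"diagnosis": np.array([[0.5, 0.5]]), "management": np.array([[0.5, 0.5]])}
        y = {t: np.array([[1.0, 0.0]]) for t in p}
        w = {t: ClassWeights(np.ones(2)) for t in p}
        assert multi_task_loss(p, y, w) == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_key_mismatch_is_an_error(self):
        p = {"a": np.array([[1.0, 0.0]])}
        y = {"b": np.array([[1.0, 0.0]])}
        w = {"a": ClassWeights(np.ones(2))}
        with pytest.raises(ValueError):
            multi_task_loss(p, y, w)


class TestBalancedMinibatch:
    def test_single_class_returns_only_that_class(self, rng):
        labels = np.full(8, 2)
        idx = sample_balanced_minibatch(labels, 5, rng)
        assert (labels[idx] == 2).all()

    def test_severe_imbalance_is_equalized(self, rng):
        labels = np.r_[np.zeros(1000, dtype=int), np.ones(10, dtype=int)]
        idx = sample_balanced_minibatch(labels, 10_000, rng)
        freq1 = labels[idx].mean()
        assert freq1 == pytest.approx(0.5, abs=0.02)

    def test_fixed_seed_reproduces_index_stream(self):
        labels = np.array([0, 0, 1, 1, 2])
        a = sample_balanced_minibatch(labels, 100, np.random.default_rng(9))
        b = sample_balanced_minibatch(labels, 100, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestTraining:
    def test_separable_toy_problem_reaches_perfect_accuracy(self):
        X = np.array([[-2.0, 0.0], [-1.5, 0.5], [1.5, -0.5], [2.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        cfg = TrainingConfig(
            batch_size=4, learning_rate=0.5, max_epochs=200, hidden_dim=0,
            task_list=("management",), seed=0,
        )
        model = train_model(X, {"management": y}, cfg, n_classes_by_task={"management": 2})
        pred = predict_proba(model, X)["management"].argmax(axis=1)
        assert (pred == y).all()

    def test_management_model_beats_majority_class_baseline(self, default_cohort):
        train = default_cohort.split("train")
        test = default_cohort.split("test")
        cfg = TrainingConfig(task_list=("management",), seed=1)
        model = train_model(design_matrix(train), {"management": train.management}, cfg)
        pred = predict_proba(model, design_matrix(test))["management"].argmax(axis=1)
        assert (pred == test.management).mean() > 605 / 1011

    def test_same_seed_gives_identical_parameters(self, default_cohort):
        train = default_cohort.split("train")
        X = design_matrix(train, "M")
        cfg = TrainingConfig(task_list=("management",), seed=5, max_epochs=10)
        m1 = train_model(X, {"management": train.management}, cfg)
        m2 = train_model(X, {"management": train.management}, cfg)
        for t in m1.task_weights:
            np.testing.assert_array_equal(m1.task_weights[t], m2.task_weights[t])
            np.testing.assert_array_equal(m1.hidden_weights[t], m2.hidden_weights[t])

    def test_nonfinite_features_and_oversized_batch_rejected(self):
        y = {"management": np.array([0, 1, 2, 0])}
        with pytest.raises(ValueError):
            train_model(np.array([[np.nan, 1.0]] * 4), y, TrainingConfig())
        with pytest.raises(ValueError):
            train_model(np.zeros((4, 2)), y, TrainingConfig(batch_size=50))

    def test_model_roundtrip(self, tmp_path, default_cohort):
        train = default_cohort.split("train")
        X = design_matrix(train, "M")
        cfg = TrainingConfig(task_list=("management",), seed=5, max_epochs=5)
        model = train_model(X, {"management": train.management}, cfg)
        model.save(tmp_path / "model.json")
        back = ModelParameters.load(tmp_path / "model.json")
        np.testing.assert_allclose(
            predict_proba(back, X)["management"], predict_proba(model, X)["management"]
        )


class TestPredictProba:
    def test_rows_are_distributions_and_zero_params_uniform(self, rng):
        model = ModelParameters(
            task_weights={"management": np.zeros((4, 3))},
            task_biases={"management": np.zeros(3)},
            hidden_weights=None,
            hidden_biases=None,
            modalities="C",
            config=TrainingConfig(hidden_dim=0),
        )
        X = rng.normal(size=(7, 4))
        P = predict_proba(model, X)["management"]
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(P, 1 / 3)

    def test_softmax_closed_form(self):
        model = ModelParameters(
            task_weights={"management": np.array([[np.log(2), 0.0]])},
            task_biases={"management": np.zeros(2)},
            hidden_weights=None,
            hidden_biases=None,
            modalities="C",
            config=TrainingConfig(hidden_dim=0),
        )
        P = predict_proba(model, np.array([[1.0]]))["management"]
        np.testing.assert_allclose(P, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_dimension_mismatch_rejected(self, default_cohort):
        train = default_cohort.split("train")
        cfg = TrainingConfig(task_list=("management",), seed=0, max_epochs=2)
        model = train_model(design_matrix(train, "M"), {"management": train.management}, cfg)
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((3, 99)))
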