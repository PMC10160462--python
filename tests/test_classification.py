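import numpy as np
import pytest

from pomhsi.classification import (
    DETECTION_ORDER,
    SEVERITY_ORDER,
    AnnModel,
    TrainingError,
    evaluate,
    one_hot,
    predict,
    split,
    train_ann,
)
from pomhsi.core import ConfigurationError


class TestOneHot:
    def test_bruised_is_one_zero(self):
        t = one_hot(["bruised"], DETECTION_ORDER)
        assert t.matrix.tolist() == [[1.0, 0.0]]

    def test_severity_coding(self):
        t = one_hot(["drop_60", "drop_100", "no_drop"], SEVERITY_ORDER)
        assert t.matrix.tolist() == [[1, 0, 0], [0, 1, 0], [0, 0, 1]]

    def test_rows_sum_to_one(self):
        labels = ["drop_60", "no_drop", "no_drop", "drop_100"] * 5
        t = one_hot(labels, SEVERITY_ORDER)
        assert np.all(t.matrix.sum(axis=1) == 1.0)
        assert t.labels == labels

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigurationError):
            one_hot(["squashed"], SEVERITY_ORDER)


class TestSplit:
    def test_90_samples_apportion_63_14_13(self):
        s = split(90, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (63, 14, 13)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    @pytest.mark.parametrize("n", [30, 60, 90, 91])
    def test_partitions_disjoint_and_exhaustive(self, n, seed):
        labels = [("a", "b", "c")[i % 3] for i in range(n)]
        s = split(n, seed=seed, labels=labels)
        union = np.concatenate([s.train, s.validation, s.test])
        assert len(union) == n
        assert len(np.unique(union)) == n

    def test_same_seed_reproduces_partition(self):
        a = split(60, seed=7)
        b = split(60, seed=7)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)

    def test_stratification_preserves_class_balance(self):
        labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        s = split(90, seed=3, labels=labels, stratify=True)
        train_labels = [labels[i] for i in s.train]
        assert sorted(set(train_labels)) == ["a", "b", "c"]
        counts = [train_labels.count(c) for c in "abc"]
        assert all(c == 21 for c in counts)  # 63 = 3 x 21

    def test_unstratified_split_supported(self):
        labels = ["a"] * 30 + ["b"] * 60
        s = split(90, seed=3, labels=labels, stratify=False)
        assert len(s.train) == 63

    def test_tiny_n_rejected(self):
        with pytest.raises(ConfigurationError):
            split(3, seed=0)


def separable_blobs(seed=0, n=40):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(-3.0, 0.3, (n // 2, 2)), rng.normal(3.0, 0.3, (n // 2, 2))]
    )
    labels = ["bruised"] * (n // 2) + ["no_bruise"] * (n // 2)
    return X, labels


class TestTrainAnn:
    def test_separable_blobs_reach_perfect_test_accuracy(self):
        X, labels = separable_blobs()
        targets = one_hot(labels, DETECTION_ORDER)
        s = split(len(labels), seed=1, labels=labels)
        model = train_ann(X, targets, s, seed=1)
        pred, _ = predict(model, X[s.test])
        truth = [labels[i] for i in s.test]
        assert evaluate(truth, pred, DETECTION_ORDER).accuracy == 100.0

    def test_identical_seeds_reproduce_loss_history(self):
        X, labels = separable_blobs(seed=5)
        targets = one_hot(labels, DETECTION_ORDER)
        s = split(len(labels), seed=2, labels=labels)
        m1 = train_ann(X, targets, s, seed=9)
        m2 = train_ann(X, targets, s, seed=9)
        assert m1.history["train_loss"] == m2.history["train_loss"]
        assert np.array_equal(m1.w_hidden, m2.w_hidden)

    def test_early_stopping_returns_best_validation_epoch(self):
        X, labels = separable_blobs(seed=3)
        targets = one_hot(labels, DETECTION_ORDER)
        s = split(len(labels), seed=3, labels=labels)
        model = train_ann(X, targets, s, max_epochs=200, patience=6, seed=3)
        hist = model.history
        assert hist["best_epoch"] <= hist["stopped_epoch"] <= 200
        assert hist["val_loss"][hist["best_epoch"] - 1] == min(hist["val_loss"])

    def test_single_class_training_partition_rejected(self):
        X = np.random.default_rng(0).normal(size=(12, 2))
        labels = ["bruised"] * 10 + ["no_bruise"] * 2
        targets = one_hot(labels, DETECTION_ORDER)
        s = split(12, seed=0, labels=labels, stratify=False)
        # force a degenerate training partition
        s.train = np.arange(8)
        with pytest.raises(TrainingError):
            train_ann(X, targets, s, seed=0)


class TestPredict:
    def hand_model(self):
        # 1 input -> 1 hidden sigmoid unit -> 2 softmax outputs
        return AnnModel(
            w_hidden=np.array([[2.0]]),
            b_hidden=np.array([-1.0]),
            w_out=np.array([[1.5, -0.5]]),
            b_out=np.array([0.1, 0.2]),
            class_order=DETECTION_ORDER,
            x_mean=np.array([0.0]),
            x_scale=np.array([1.0]),
        )

    def test_probabilities_sum_to_one(self):
        model = self.hand_model()
        _, probs = predict(model, np.linspace(-2, 2, 7).reshape(-1, 1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_hand_computed_sigmoid_softmax_chain(self):
        model = self.hand_model()
        x = 1.2
        h = 1.0 / (1.0 + np.exp(-(2.0 * x - 1.0)))
        z = np.array([1.5 * h + 0.1, -0.5 * h + 0.2])
        expected = np.exp(z) / np.exp(z).sum()
        _, probs = predict(model, np.array([[x]]))
        assert np.allclose(probs[0], expected, atol=1e-12)

    def test_tie_breaks_to_earlier_class(self):
        model = self.hand_model()
        model.w_out = np.array([[0.0, 0.0]])
        model.b_out = np.array([0.3, 0.3])  # exactly uniform output
        labels, probs = predict(model, np.array([[0.5]]))
        assert np.allclose(probs[0], 0.5)
        assert labels == ["bruised"]

    def test_dimension_mismatch_rejected(self):
        from pomhsi.core import ShapeError

        with pytest.raises(ShapeError):
            predict(self.hand_model(), np.zeros((3, 2)))


class TestEvaluate:
    def test_combined_severity_worked_example(self):
        """A 3-class matrix with diagonal (25, 25, 30) over 90 samples gives
        88.9% overall accuracy and 11.1% class error."""
        order = SEVERITY_ORDER
        truth, pred = [], []
        # 25/30, 25/30, 30/30 correct; misclassifications spread arbitrarily
        for cls, correct in zip(order, (25, 25, 30)):
            truth += [cls] * 30
            wrong = [c for c in order if c != cls][0]
            pred += [cls] * correct + [wrong] * (30 - correct)
        rep = evaluate(truth, pred, order)
        assert np.trace(rep.matrix) == 80 and rep.total == 90
        assert rep.accuracy == pytest.approx(88.888888, abs=1e-3)
        assert rep.class_error == pytest.approx(11.111111, abs=1e-3)
        assert round(rep.accuracy, 1) == 88.9 and round(rep.class_error, 1) == 11.1

    def test_per_class_accuracy_29_of_30(self):
        truth = ["no_bruise"] * 30
        pred = ["no_bruise"] * 29 + ["bruised"]
        rep = evaluate(truth, pred, DETECTION_ORDER)
        assert rep.per_class_accuracy["no_bruise"] == pytest.approx(96.666666, abs=1e-3)
        assert round(rep.per_class_accuracy["no_bruise"], 1) == 96.7

    def test_row_sums_equal_true_class_counts(self):
        rng = np.random.default_rng(0)
        truth = [SEVERITY_ORDER[i] for i in rng.integers(0, 3, 60)]
        pred = [SEVERITY_ORDER[i] for i in rng.integers(0, 3, 60)]
        rep = evaluate(truth, pred, SEVERITY_ORDER)
        for i, c in enumerate(SEVERITY_ORDER):
            assert rep.matrix[i].sum() == truth.count(c)
        assert rep.accuracy + rep.class_error == pytest.approx(100.0)

    def test_perfect_prediction(self):
        truth = ["drop_60", "drop_100", "no_drop"] * 4
        rep = evaluate(truth, truth, SEVERITY_ORDER)
        assert rep.accuracy == 100.0
        assert np.all(rep.matrix == np.diag(rep.matrix.diagonal()))

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate(["x"], ["no_drop"], SEVERITY_ORDER)


class TestModelSerialization:
    def test_roundtrip_through_dict(self):
        X, labels = separable_blobs(seed=8)
        targets = one_hot(labels, DETECTION_ORDER)
        s = split(len(labels), seed=4, labels=labels)
        model = train_ann(X, targets, s, seed=4)
        back = AnnModel.from_dict(model.to_dict())
        p1, _ = predict(model, X)
        p2, _ = predict(back, X)
        assert p1 == p2
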