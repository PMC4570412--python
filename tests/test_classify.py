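"""Classifier training, prediction, and validation protocols."""

import numpy as np
import pytest

import fmakit as fk
from fmakit.classify import hidden_layer_size

from conftest import separable_dataset


class TestSvm:
    def test_separable_clusters_reach_full_training_accuracy(self):
        data = separable_dataset(n_per_class=5, sd=0.01, spacing=10.0, seed=1)
        model = fk.train_svm(data)
        preds = [model.predict(x) for x in data.X]
        assert fk.accuracy(preds, data.y) == 1.0

    def test_single_class_data_rejected(self):
        data = separable_dataset()
        single = data.subset(data.y == 1)
        with pytest.raises(fk.TrainingError):
            fk.train_svm(single)

    def test_dimension_mismatch_at_predict_time(self):
        model = fk.train_svm(separable_dataset(dim=3))
        with pytest.raises(fk.ValidationError, match="dimension"):
            model.predict(np.zeros(4))

    def test_duplicated_training_set_gives_same_decision_function(self):
        data = separable_dataset(seed=2)
        doubled = fk.LabeledDataset(
            X=np.vstack([data.X, data.X]),
            y=np.concatenate([data.y, data.y]),
            subjects=data.subjects * 2,
            test_id=data.test_id,
        )
        m1, m2 = fk.train_svm(data), fk.train_svm(doubled)
        rng = np.random.default_rng(0)
        for x in rng.normal(10.0, 8.0, size=(50, 3)):
            np.testing.assert_allclose(
                m1.decision_values(x)[1], m2.decision_values(x)[1], atol=1e-6
            )

    def test_middle_class_is_learnable_on_amplitude_like_features(self):
        # score 1 lies between scores 0 and 2 on every axis; pairwise linear
        # machines must still separate it
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(c * 5.0, 0.2, size=(8, 2)) for c in range(3)])
        y = np.repeat([0, 1, 2], 8)
        data = fk.LabeledDataset(X=X, y=y, subjects=[f"P{i%8}" for i in range(24)],
                                 test_id="toy")
        model = fk.train_svm(data)
        assert fk.accuracy([model.predict(x) for x in X], y) == 1.0

    def test_nearest_centroid_oracle_agreement(self):
        data = separable_dataset(n_per_class=8, sd=0.05, spacing=12.0, seed=3)
        model = fk.train_svm(data)
        centroids = np.array([data.X[data.y == c].mean(axis=0) for c in range(3)])
        rng = np.random.default_rng(1)
        probes = rng.normal(12.0, 10.0, size=(100, 3))
        for x in probes:
            expected = int(np.argmin(np.linalg.norm(centroids - x, axis=1)))
            assert model.predict(x) == expected

    def test_model_json_round_trip(self, tmp_path):
        data = separable_dataset(seed=4)
        model = fk.train_svm(data)
        model.save(tmp_path / "m.json")
        loaded = fk.ClassifierModel.load(tmp_path / "m.json")
        for x in data.X:
            assert loaded.predict(x) == model.predict(x)


class TestBnn:
    def test_hidden_layer_halfway_rule(self):
        assert hidden_layer_size(7) == 5  # the worked seven-feature case
        assert hidden_layer_size(1) == 2
        assert hidden_layer_size(6) == 5  # 4.5 rounds half-up

    def test_deterministic_given_seed(self):
        data = separable_dataset(seed=6)
        m1 = fk.train_bnn(data, seed=42, epochs=50)
        m2 = fk.train_bnn(data, seed=42, epochs=50)
        for key in ("W1", "b1", "W2", "b2"):
            np.testing.assert_array_equal(m1.params[key], m2.params[key])

    def test_different_seeds_differ(self):
        data = separable_dataset(seed=6)
        m1 = fk.train_bnn(data, seed=1, epochs=10)
        m2 = fk.train_bnn(data, seed=2, epochs=10)
        assert not np.array_equal(m1.params["W1"], m2.params["W1"])

    def test_converges_on_separable_clusters(self):
        data = separable_dataset(n_per_class=5, sd=0.01, spacing=10.0, seed=1)
        model = fk.train_bnn(data, seed=0, epochs=2000)
        preds = [model.predict(x) for x in data.X]
        assert fk.accuracy(preds, data.y) == 1.0

    def test_agrees_with_independent_gradient_descent(self):
        # independent loop-based backprop implementation, same init and data
        data = separable_dataset(n_per_class=4, sd=0.05, spacing=6.0, seed=9)
        epochs, lr = 120, 0.7
        model = fk.train_bnn(data, seed=3, epochs=epochs, learning_rate=lr)

        d = data.X.shape[1]
        h = hidden_layer_size(d)
        rng = np.random.default_rng(3)
        lim1, lim2 = np.sqrt(6.0 / (d + h)), np.sqrt(6.0 / (h + 3))
        w1 = rng.uniform(-lim1, lim1, size=(d, h))
        w2 = rng.uniform(-lim2, lim2, size=(h, 3))
        b1, b2 = np.zeros(h), np.zeros(3)
        mu, sd_ = data.X.mean(0), data.X.std(0)
        sd_[sd_ < 1e-12] = 1.0
        xn = (data.X - mu) / sd_
        t = np.eye(3)[data.y]

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        n = len(xn)
        for _ in range(epochs):
            gw1 = np.zeros_like(w1); gb1 = np.zeros_like(b1)
            gw2 = np.zeros_like(w2); gb2 = np.zeros_like(b2)
            for i in range(n):  # per-sample accumulation, then averaged
                hid = sig(xn[i] @ w1 + b1)
                out = sig(hid @ w2 + b2)
                do = (out - t[i]) * out * (1 - out)
                dh = (w2 @ do) * hid * (1 - hid)
                gw2 += np.outer(hid, do); gb2 += do
                gw1 += np.outer(xn[i], dh); gb1 += dh
            w2 -= lr * gw2 / n; b2 -= lr * gb2 / n
            w1 -= lr * gw1 / n; b1 -= lr * gb1 / n

        np.testing.assert_allclose(model.params["W1"], w1, atol=1e-9)
        np.testing.assert_allclose(model.params["W2"], w2, atol=1e-9)

    def test_bad_hyperparameters_rejected(self):
        data = separable_dataset()
        with pytest.raises(fk.ParameterError):
            fk.train_bnn(data, seed=0, epochs=0)
        with pytest.raises(fk.ParameterError):
            fk.train_bnn(data, seed=0, learning_rate=-1.0)

    def test_tie_on_equal_activations_predicts_lowest_score(self):
        model = fk.ClassifierModel(
            kind="bnn", test_id="toy", dimension=2,
            params={"W1": np.zeros((2, 3)), "b1": np.zeros(3),
                    "W2": np.zeros((3, 3)), "b2": np.zeros(3),
                    "mu": np.zeros(2), "sd": np.ones(2)},
        )
        assert model.predict(np.array([0.3, -0.7])) == 0


class TestLabelPermutation:
    @pytest.mark.parametrize("trainer", ["svm", "bnn"])
    def test_relabeling_classes_permutes_predictions(self, trainer):
        data = separable_dataset(n_per_class=6, sd=0.05, spacing=8.0, seed=7)
        perm = {0: 2, 1: 0, 2: 1}
        permuted = fk.LabeledDataset(
            X=data.X, y=np.array([perm[c] for c in data.y]),
            subjects=data.subjects, test_id=data.test_id,
        )
        kw = {"seed": 0} if trainer == "bnn" else {}
        m1 = getattr(fk, f"train_{trainer}")(data, **kw)
        m2 = getattr(fk, f"train_{trainer}")(permuted, **kw)
        for x in data.X:
            assert m2.predict(x) == perm[m1.predict(x)]


class TestAccuracy:
    def test_identical_and_disjoint_lists(self):
        assert fk.accuracy([0, 1, 2], [0, 1, 2]) == 1.0
        assert fk.accuracy([0, 0, 0], [1, 2, 1]) == 0.0

    def test_fractional_counting(self):
        preds = [1] * 29 + [0]
        truth = [1] * 30
        assert fk.accuracy(preds, truth) == pytest.approx(29 / 30)

    def test_length_mismatch_rejected(self):
        with pytest.raises(fk.ParameterError):
            fk.accuracy([0], [0, 1])


class TestCrossValBySubject:
    def test_fold_count_equals_subject_count(self):
        data = separable_dataset(n_per_class=6, n_subjects=6, seed=8)
        res = fk.crossval_by_subject(data, trainer="svm")
        assert res.n_folds == 6
        assert set(res.per_subject) == {f"P{i}" for i in range(6)}

    def test_identical_separable_subjects_score_perfectly(self):
        data = separable_dataset(n_per_class=2, n_subjects=2, sd=0.01, seed=9)
        res = fk.crossval_by_subject(data, trainer="svm")
        assert all(a == 1.0 for a in res.per_subject.values())

    def test_shuffled_labels_hit_chance_level(self):
        rng = np.random.default_rng(12345)
        n = 300
        X = rng.normal(size=(n, 4))
        y = np.repeat([0, 1, 2], n // 3)
        rng.shuffle(y)
        data = fk.LabeledDataset(
            X=X, y=y, subjects=[f"P{i % 10}" for i in range(n)], test_id="null"
        )
        res = fk.crossval_by_subject(data, trainer="svm")
        assert res.mean == pytest.approx(1 / 3, abs=0.06)

    def test_single_class_fold_skipped_with_warning(self):
        X = np.array([[0.0], [0.0], [1.0]])
        data = fk.LabeledDataset(X=X, y=np.array([1, 1, 2]),
                                 subjects=["A", "A", "B"], test_id="toy")
        with pytest.warns(UserWarning, match="single-class"):
            res = fk.crossval_by_subject(data, trainer="svm")
        assert "B" in res.skipped and res.n_folds == 2


class TestTrainingCurve:
    def test_full_sample_single_rep_equals_training_accuracy(self):
        data = separable_dataset(n_per_class=5, sd=0.01, seed=10)
        curve = fk.training_curve(data, instances_per_class=[5], reps=1, seed=0)
        model = fk.train_svm(data)
        expected = fk.accuracy([model.predict(x) for x in data.X], data.y)
        assert curve[5] == expected == 1.0

    def test_more_instances_help_on_noisy_cohort(self):
        rng = np.random.default_rng(77)
        X = np.concatenate(
            [rng.normal(c * 2.0, 1.0, size=(40, 2)) for c in range(3)]
        )
        y = np.repeat([0, 1, 2], 40)
        data = fk.LabeledDataset(X=X, y=y,
                                 subjects=[f"P{i % 10}" for i in range(120)],
                                 test_id="noisy")
        curve = fk.training_curve(data, instances_per_class=[1, 5], reps=50, seed=0)
        assert curve[5] >= curve[1]

    def test_deterministic_given_seed(self):
        data = separable_dataset(n_per_class=8, sd=0.5, seed=11)
        c1 = fk.training_curve(data, [2, 4], reps=5, seed=3)
        c2 = fk.training_curve(data, [2, 4], reps=5, seed=3)
        assert c1 == c2

    def test_oversized_request_rejected(self):
        data = separable_dataset(n_per_class=3)
        with pytest.raises(fk.ParameterError):
            fk.training_curve(data, [10], reps=1, seed=0)
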