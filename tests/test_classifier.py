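"""Loss, ensemble, metrics and recommendation logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sansml import classifier as C
from sansml import nn
from sansml.exceptions import DomainError, ValidationError


class TestCrossEntropy:
    def test_uniform_logits_over_46_classes(self):
        assert C.cross_entropy_loss(np.zeros(46), 7) == pytest.approx(np.log(46), rel=1e-12)

    def test_three_class_reference_value(self):
        v = C.cross_entropy_loss([1.0, 0.0, 0.0], 0)
        assert v == pytest.approx(-np.log(np.e / (np.e + 2)), rel=1e-12)

    def test_loss_vanishes_as_correct_logit_grows(self):
        losses = [C.cross_entropy_loss([a, 0.0, 0.0], 0) for a in (0, 2, 5, 20, 200)]
        assert all(np.diff(losses) < 0)
        assert losses[-1] == pytest.approx(0.0, abs=1e-12)

    def test_label_out_of_range(self):
        with pytest.raises(DomainError):
            C.cross_entropy_loss([0.0, 1.0], 2)


class TestTopK:
    def test_k_equals_c_is_always_one(self, rng):
        probs = rng.random((20, 7))
        labels = rng.integers(0, 7, 20)
        assert C.topk_accuracy(probs, labels, 7) == 1.0

    def test_rank_enumeration(self):
        probs = np.array([
            [0.5, 0.3, 0.2],   # label 0 ranked 1st
            [0.5, 0.3, 0.2],   # label 2 ranked 3rd
            [0.5, 0.3, 0.2],   # label 1 ranked 2nd
        ])
        labels = np.array([0, 2, 1])
        assert C.topk_accuracy(probs, labels, 1) == pytest.approx(1 / 3)
        assert C.topk_accuracy(probs, labels, 2) == pytest.approx(2 / 3)
        assert C.topk_accuracy(probs, labels, 3) == 1.0

    def test_tie_break_toward_lowest_index(self):
        probs = np.array([[0.4, 0.4, 0.2]])
        assert C.topk_accuracy(probs, np.array([0]), 1) == 1.0
        assert C.topk_accuracy(probs, np.array([1]), 1) == 0.0

    @given(st.integers(1, 6))
    @settings(max_examples=10, deadline=None)
    def test_topk_monotone_in_k(self, k):
        g = np.random.default_rng(0)
        probs = g.random((50, 6))
        labels = g.integers(0, 6, 50)
        accs = [C.topk_accuracy(probs, labels, kk) for kk in range(1, 7)]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))
        assert C.topk_accuracy(probs, labels, k) == accs[k - 1]


class TestEnsemble:
    def _dummy_member(self, seed, n_classes=4):
        cfg = C.TrainingConfig(seed=seed, n_classes=n_classes)
        return C.TrainedModel(net=nn.build_compact_cnn(n_classes, seed=seed), config=cfg)

    def test_single_member_identity(self, rng):
        m = self._dummy_member(0)
        img = rng.random((180, 180)).astype(np.float32)
        a = C.predict_proba(m, img)
        b = C.ensemble_proba([m], img)
        assert np.allclose(a, b)

    def test_hand_average(self):
        assert np.allclose(
            np.mean([np.array([0.6, 0.4]), np.array([0.2, 0.8])], axis=0), [0.4, 0.6]
        )
        m1, m2 = self._dummy_member(1), self._dummy_member(2)
        img = np.random.default_rng(0).random((180, 180)).astype(np.float32)
        avg = C.ensemble_proba([m1, m2], img)
        assert np.allclose(avg, (C.predict_proba(m1, img) + C.predict_proba(m2, img)) / 2)
        assert avg.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_class_counts_rejected(self):
        with pytest.raises(ValidationError):
            C.EnsembleModel([self._dummy_member(0, 4), self._dummy_member(1, 5)])

    def test_identical_members_equal_single(self, rng):
        m = self._dummy_member(3)
        img = rng.random((180, 180)).astype(np.float32)
        assert np.allclose(C.ensemble_proba([m, m, m], img), C.predict_proba(m, img))

    def test_probability_vector_contract(self, rng):
        m = self._dummy_member(4)
        probs = C.predict_proba(m, rng.random((5, 180, 180)).astype(np.float32))
        assert probs.shape == (5, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_wrong_input_shape_rejected(self):
        with pytest.raises(ValidationError):
            C.predict_proba(self._dummy_member(0), np.zeros((100, 100), dtype=np.float32))


class TestReports:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 2, 1])
        rep = C.classification_report(y, y, n_classes=3)
        assert np.allclose(rep["precision"], 1.0)
        assert np.allclose(rep["recall"], 1.0)
        assert np.allclose(rep["f1"], 1.0)
        cm = C.confusion_matrix(y, y, n_classes=3)
        assert np.array_equal(cm, np.diag([1, 2, 2]))

    def test_two_class_contingency(self):
        preds = np.array([1, 1, 0, 0])
        labels = np.array([1, 0, 0, 0])
        rep = C.classification_report(preds, labels, n_classes=2)
        assert rep.loc[0, "precision"] == pytest.approx(1.0)
        assert rep.loc[0, "recall"] == pytest.approx(2 / 3)
        assert rep.loc[1, "precision"] == pytest.approx(0.5)
        assert rep.loc[1, "recall"] == pytest.approx(1.0)

    def test_f1_zero_when_precision_zero(self):
        preds = np.array([1, 1])
        labels = np.array([0, 0])
        rep = C.classification_report(preds, labels, n_classes=2)
        assert rep.loc[1, "precision"] == 0.0
        assert rep.loc[1, "f1"] == 0.0

    def test_absent_class_flagged_with_nan(self):
        preds = np.array([0, 0])
        labels = np.array([0, 0])
        rep = C.classification_report(preds, labels, n_classes=3)
        assert rep.loc[2, "support"] == 0
        assert np.isnan(rep.loc[2, "precision"]) and np.isnan(rep.loc[2, "recall"])

    def test_confusion_matrix_conserves_counts(self, rng):
        n, c = 200, 6
        preds = rng.integers(0, c, n)
        labels = rng.integers(0, c, n)
        cm = C.confusion_matrix(preds, labels, n_classes=c)
        assert cm.sum() == n
        assert np.array_equal(cm.sum(axis=1), np.bincount(labels, minlength=c))

    def test_report_and_confusion_mutually_consistent(self, rng):
        """precision/recall recomputed from the confusion matrix must agree."""
        c = 5
        preds = rng.integers(0, c, 300)
        labels = rng.integers(0, c, 300)
        rep = C.classification_report(preds, labels, n_classes=c)
        cm = C.confusion_matrix(preds, labels, n_classes=c)
        for k in range(c):
            tp = cm[k, k]
            col, row = cm[:, k].sum(), cm[k, :].sum()
            if col:
                assert rep.loc[k, "precision"] == pytest.approx(tp / col)
            if row:
                assert rep.loc[k, "recall"] == pytest.approx(tp / row)


class TestTraining:
    def _separable_data(self, n_per=24):
        """Two synthetic classes: bright left half vs bright right half."""
        g = np.random.default_rng(0)
        X = g.random((2 * n_per, 180, 180)).astype(np.float32) * 0.1
        X[:n_per, :, :90] += 0.8
        X[n_per:, :, 90:] += 0.8
        y = np.repeat([0, 1], n_per)
        idx = g.permutation(len(y))
        return X[idx], y[idx]

    def test_learns_separable_task_and_checkpoints(self):
        X, y = self._separable_data()
        cfg = C.TrainingConfig(epochs=4, lr=1e-3, seed=0, n_classes=2, batch_size=16)
        model = C.train_model("compact", (X[:32], y[:32]), (X[32:], y[32:]), cfg)
        assert len(model.history["test_acc"]) <= 4
        assert model.history["train_loss"][-1] <= model.history["train_loss"][0]
        assert max(model.history["test_acc"]) >= 0.95
        # nearest-centroid oracle confirms the task is separable
        mu0 = X[y == 0].mean(axis=0).ravel()
        mu1 = X[y == 1].mean(axis=0).ravel()
        d0 = np.linalg.norm(X.reshape(len(X), -1) - mu0, axis=1)
        d1 = np.linalg.norm(X.reshape(len(X), -1) - mu1, axis=1)
        assert np.mean((d1 < d0) == (y == 1)) == 1.0

    def test_single_class_warns(self):
        X, y = self._separable_data(8)
        y0 = np.zeros_like(y)
        cfg = C.TrainingConfig(epochs=1, lr=1e-3, seed=0, n_classes=2, batch_size=8)
        with pytest.warns(UserWarning, match="single-class"):
            C.train_model("compact", (X, y0), (X, y0), cfg)

    def test_unknown_architecture_rejected(self):
        X, y = self._separable_data(4)
        with pytest.raises(ValidationError, match="architecture"):
            C.train_model("resnet50", (X, y), (X, y))


class TestRecommendation:
    def test_full_ranking_sums_to_one(self, rng):
        cfg = C.TrainingConfig(seed=0, n_classes=46)
        m = C.TrainedModel(net=nn.build_compact_cnn(46, seed=0), config=cfg)
        ens = C.EnsembleModel([m])
        raw = rng.random((144, 256)) * 10
        rec = C.recommend(ens, raw, k=46)
        scores = [s for _, s in rec.ranked]
        assert sum(scores) == pytest.approx(1.0, abs=1e-6)
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert rec.baseline == pytest.approx(1 / 46, abs=1e-9)
        assert len(rec.member_ranked) == 1

    def test_negative_pixels_propagate_error(self):
        cfg = C.TrainingConfig(seed=0, n_classes=46)
        m = C.TrainedModel(net=nn.build_compact_cnn(46, seed=0), config=cfg)
        with pytest.raises(ValidationError):
            C.recommend(C.EnsembleModel([m]), -np.ones((144, 256)))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = C.TrainingConfig(seed=5, n_classes=4)
        m = C.TrainedModel(net=nn.build_compact_cnn(4, seed=5), config=cfg,
                           history={"test_acc": [0.5]}, best_epoch=0)
        path = C.save_model(m, tmp_path / "member")
        back = C.load_model(path)
        img = rng.random((180, 180)).astype(np.float32)
        assert np.allclose(C.predict_proba(m, img), C.predict_proba(back, img))
        assert back.config.seed == 5 and back.best_epoch == 0
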