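"""Cross-validation machinery, oversampling, metrics, CNN and UMAP."""

import logging

import numpy as np
import pytest

from vibrouroflow import CnnClassifier, CvConfig, PatternLabel
from vibrouroflow.classifier import (_oversample_indices, evaluate,
                                     kfold_split, oversample, run_cv,
                                     train_model, umap_embed)
from vibrouroflow.errors import (DegenerateFoldError, InsufficientDataError)
from vibrouroflow.types import SessionRecord, VibrationRecord


def fake_session(label, idx=0):
    return SessionRecord(
        session_id=f"F{label}-{idx}",
        vibration=VibrationRecord(fs=100.0, samples=np.zeros(10)),
        label=PatternLabel(label))


def toy_features(n_per_class=6, n_classes=6, t=32, f=13, seed=0, sep=4.0):
    """Linearly separable toy spectrograms: each class gets energy in its
    own temporal slot."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            m = rng.standard_normal((t, f)).astype(np.float32) * 0.3
            lo = c * (t // n_classes)
            m[lo:lo + t // n_classes] += sep
            X.append(m)
            y.append(c)
    return np.stack(X), np.asarray(y)


class TestKfold:
    def test_partition_arithmetic(self):
        y = np.repeat(np.arange(5), 2)  # n=10, 2 per class
        folds = kfold_split(y, CvConfig(k=5, shuffle_seed=1))
        assert len(folds) == 5
        all_test = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(all_test, np.arange(10))
        assert all(te.size == 2 for _, te in folds)
        for tr, te in folds:
            assert np.intersect1d(tr, te).size == 0

    def test_deterministic(self):
        y = np.repeat(np.arange(6), 10)
        a = kfold_split(y, CvConfig(k=5, shuffle_seed=3))
        b = kfold_split(y, CvConfig(k=5, shuffle_seed=3))
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_too_small_cohort(self):
        with pytest.raises(InsufficientDataError):
            kfold_split(np.array([0, 1, 2]), CvConfig(k=5))

    def test_unstratified_fallback_warns(self, caplog):
        y = np.array([0] * 8 + [1] * 2)  # class 1 has fewer than k members
        with caplog.at_level(logging.WARNING):
            folds = kfold_split(y, CvConfig(k=5, shuffle_seed=0))
        assert len(folds) == 5
        assert any("fewer than k" in r.message for r in caplog.records)


class TestOversample:
    def test_reference_counts(self):
        """Training counts 18/38/4/5/9/2 with target=majority rebalance the
        requested minority labels to 38 and leave the rest alone."""
        train = [fake_session(lab, i)
                 for lab, n in {0: 18, 1: 38, 2: 4, 3: 5, 4: 9, 5: 2}.items()
                 for i in range(n)]
        out = oversample(train, CvConfig(), np.random.default_rng(0))
        counts = {lab: sum(1 for s in out if int(s.label) == lab)
                  for lab in range(6)}
        assert counts == {0: 18, 1: 38, 2: 38, 3: 38, 4: 9, 5: 38}

    def test_duplicates_share_objects(self):
        train = [fake_session(lab, i) for lab in (1, 2) for i in range(3)] \
            + [fake_session(1, 9) for _ in range(3)]
        out = oversample(train, CvConfig(oversample_labels=frozenset({2})),
                         np.random.default_rng(0))
        originals = {id(s) for s in train}
        assert all(id(s) in originals for s in out)

    def test_empty_label_set_is_identity(self):
        train = [fake_session(0, i) for i in range(3)] + [fake_session(1, 0)]
        out = oversample(train, CvConfig(oversample_labels=frozenset()),
                         np.random.default_rng(0))
        assert out == train

    def test_balanced_input_unchanged(self):
        y = np.repeat(np.arange(6), 4)
        idx = _oversample_indices(y, CvConfig(), np.random.default_rng(0))
        assert np.array_equal(idx, np.arange(24))

    def test_absent_label_is_skipped_with_warning(self, caplog):
        y = np.array([0, 0, 0, 1, 1])
        with caplog.at_level(logging.WARNING):
            idx = _oversample_indices(y, CvConfig(), np.random.default_rng(0))
        assert any("absent" in r.message for r in caplog.records)
        # label 1 (in the oversample set? no) -> only {2,3,5} requested, all absent
        assert np.array_equal(np.sort(idx), np.arange(5))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(6), 3)
        m = evaluate(lambda X: y, np.zeros((18, 2, 2)), y)
        assert m.precision == m.recall == m.f1 == 1.0
        assert np.array_equal(m.confusion, np.diag([3] * 6))

    def test_hand_computed_two_class_confusion(self):
        # TP=9, FP=1, FN=1, TN=9 -> precision = recall = F1 = 0.9
        y = np.array([0] * 10 + [1] * 10)
        pred = y.copy()
        pred[0] = 1   # one class-0 example called 1
        pred[10] = 0  # one class-1 example called 0
        m = evaluate(lambda X: pred, np.zeros((20, 2, 2)), y)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)

    def test_constant_predictor_on_balanced_classes(self):
        y = np.repeat(np.arange(6), 4)
        m = evaluate(lambda X: np.zeros_like(y), np.zeros((24, 2, 2)), y)
        assert m.per_class[0]["recall"] == 1.0
        assert all(m.per_class[c]["recall"] == 0.0 for c in range(1, 6))
        assert m.recall == pytest.approx(1 / 6)

    def test_macro_metrics_invariant_to_label_permutation(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 6, 60)
        pred = rng.integers(0, 6, 60)
        perm = rng.permutation(6)
        m1 = evaluate(lambda X: pred, np.zeros((60, 2, 2)), y)
        m2 = evaluate(lambda X: perm[pred], np.zeros((60, 2, 2)), perm[y])
        assert m1.macro_f1 == pytest.approx(m2.macro_f1)
        assert m1.macro_precision == pytest.approx(m2.macro_precision)

    def test_empty_test_fold(self):
        with pytest.raises(InsufficientDataError):
            evaluate(lambda X: X, np.zeros((0, 2, 2)), np.array([]))

    def test_confusion_rows_equal_class_counts(self):
        y = np.repeat(np.arange(6), 5)
        pred = np.roll(y, 3)
        m = evaluate(lambda X: pred, np.zeros((30, 2, 2)), y)
        assert np.array_equal(m.confusion.sum(axis=1), np.full(6, 5))


class TestCnn:
    def test_separable_toy_reaches_full_training_accuracy(self):
        X, y = toy_features(n_per_class=5, n_classes=2, t=16, sep=3.0)
        m = CnnClassifier(n_classes=2, epochs=12, seed=0, batch_size=8)
        m.fit(X, y)
        assert (m.predict(X) == y).mean() == 1.0

    def test_seeded_runs_are_identical(self):
        X, y = toy_features(n_per_class=4, n_classes=3, t=16)
        p1 = CnnClassifier(n_classes=3, epochs=4, seed=11).fit(X, y).predict_proba(X)
        p2 = CnnClassifier(n_classes=3, epochs=4, seed=11).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_fold_rejected(self):
        X = np.zeros((8, 16, 13), dtype=np.float32)
        y = np.zeros(8, dtype=int)
        with pytest.raises(DegenerateFoldError):
            train_model(X, y, CvConfig(epochs=1))


class TestRunCv:
    def test_five_folds_five_reports(self):
        X, y = toy_features(n_per_class=10, n_classes=6, t=24)
        cfg = CvConfig(k=5, epochs=3, shuffle_seed=0, model_seed=0)
        rep = run_cv((X, y), cfg)
        assert len(rep.per_fold) == 5
        assert rep.aggregate.n_test == 60
        assert rep.aggregate.confusion.sum() == 60

    def test_deterministic_reports(self):
        X, y = toy_features(n_per_class=6, n_classes=6, t=24)
        cfg = CvConfig(k=3, epochs=2, shuffle_seed=4, model_seed=4)
        r1 = run_cv((X, y), cfg)
        r2 = run_cv((X, y), cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_aggregate_is_fold_mean(self):
        X, y = toy_features(n_per_class=6, n_classes=6, t=24)
        rep = run_cv((X, y), CvConfig(k=3, epochs=2, shuffle_seed=1, model_seed=1))
        assert rep.aggregate.f1 == pytest.approx(
            np.mean([m.f1 for m in rep.per_fold]))


class TestUmap:
    def test_duplicate_sessions_stay_adjacent(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 64)).astype(np.float32)
        X[5] = X[4]  # duplicated session
        emb = umap_embed(X, seed=0)
        assert emb.coords.shape == (40, 2)
        d = np.linalg.norm(emb.coords - emb.coords[5], axis=1)
        d[5] = np.inf
        # the duplicate is its twin's nearest neighbor in the embedding
        assert int(np.argmin(d)) == 4
        from scipy.spatial.distance import pdist
        assert d[4] <= np.percentile(pdist(emb.coords), 5)

    def test_separated_classes_keep_positive_silhouette(self):
        X, y = toy_features(n_per_class=10, n_classes=3, t=16, sep=6.0)
        emb = umap_embed(X.reshape(X.shape[0], -1), seed=0, labels=y)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(emb.coords, y) > 0

    def test_too_few_sessions(self):
        with pytest.raises(InsufficientDataError):
            umap_embed(np.zeros((5, 4)), seed=0)
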