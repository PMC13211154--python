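"""Cross-validation protocol: fold assignment, leakage guards, metric
identities, early stopping, and the median-fold rule."""

import numpy as np
import pytest

from edapain import evalcv
from edapain.evalcv import (
    FoldAssignment,
    LeakageError,
    TrainSettings,
    assign_folds,
    cross_validate,
    evaluate,
    fold_split,
    train_model,
)
from edapain.fcn import ConvBlock, FcnConfig, build_fcn
from edapain.labels import Label
from edapain.metrics import compute_metrics
from edapain.preprocess import Window, WindowSet

TINY = FcnConfig(input_len=50, conv_blocks=(ConvBlock(4, 2, "relu", True),), avgpool_kernel=2)


def synthetic_windowset(n_subjects=10, per_class=3, win_len=50, sep=2.0, seed=0):
    """Separable toy windows: a class-dependent step in the second half of
    the window (structure, not a DC offset) + small noise."""
    rng = np.random.default_rng(seed)
    ws = WindowSet()
    for s in range(n_subjects):
        for label in Label:
            for _ in range(per_class):
                x = rng.normal(size=win_len) * 0.3
                x[win_len // 2 :] += float(label) * sep
                ws.windows.append(Window(f"P{s:02d}", label, 0, x))
    return ws


class TestAssignFolds:
    def test_65_subjects_five_folds_of_13(self):
        folds = assign_folds([f"S{i}" for i in range(65)], k=5, seed=0)
        sizes = [len(folds.subjects_in(f)) for f in range(1, 6)]
        assert sizes == [13] * 5

    def test_one_subject_per_fold(self):
        folds = assign_folds(list("abcde"), k=5, seed=1)
        assert sorted(len(folds.subjects_in(f)) for f in range(1, 6)) == [1] * 5

    def test_every_subject_in_exactly_one_fold(self):
        ids = [f"S{i}" for i in range(23)]
        folds = assign_folds(ids, k=5, seed=3)
        assert sorted(folds.mapping) == sorted(ids)
        sizes = [len(folds.subjects_in(f)) for f in range(1, 6)]
        assert max(sizes) - min(sizes) <= 1

    def test_seed_determinism(self):
        ids = [f"S{i}" for i in range(20)]
        assert assign_folds(ids, seed=9).mapping == assign_folds(ids, seed=9).mapping
        assert assign_folds(ids, seed=9).mapping != assign_folds(ids, seed=10).mapping

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], k=5)


class TestFoldSplit:
    def test_rotation_rule_and_sizes(self):
        folds = assign_folds([f"S{i}" for i in range(10)], k=5, seed=0)
        for test_fold in range(1, 6):
            train, val, test = fold_split(folds, test_fold)
            expected_val = (test_fold % 5) + 1
            assert val == set(folds.subjects_in(expected_val))
            assert len(train) == 6 and len(val) == 2 and len(test) == 2

    def test_pairwise_disjoint_guard(self):
        folds = FoldAssignment({"a": 1, "b": 1, "c": 2, "d": 3, "e": 4, "f": 5}, k=5)
        for test_fold in range(1, 6):
            train, val, test = fold_split(folds, test_fold)
            assert not train & val and not train & test and not val & test

    def test_leakage_error_on_overlap(self):
        with pytest.raises(LeakageError):
            evalcv.check_disjoint(train={"a", "b"}, test={"b"})


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        report = compute_metrics(y, y)
        assert report.accuracy == 1.0
        assert np.array_equal(report.confusion, np.eye(3))
        assert report.weighted_f1 == 1.0

    def test_hand_computed_weighted_metrics_all_one_class(self):
        """10 samples (4 NP, 3 LP, 3 HP), every prediction NP."""
        y_true = np.array([0] * 4 + [1] * 3 + [2] * 3)
        y_pred = np.zeros(10, dtype=int)
        r = compute_metrics(y_true, y_pred)
        assert r.accuracy == pytest.approx(0.4)
        # precision: NP 4/10, others 0 -> weighted = 0.4*0.4
        assert r.weighted_precision == pytest.approx(0.4 * 0.4)
        # F1(NP) = 2*0.4*1/(1.4); weighted = 0.4 * that
        assert r.weighted_f1 == pytest.approx(0.4 * (2 * 0.4 / 1.4))

    def test_single_class_test_set_confusion_row(self):
        r = compute_metrics(np.array([2, 2, 2]), np.array([2, 1, 2]))
        assert r.confusion[2].sum() == pytest.approx(1.0)
        assert r.confusion[0].sum() == 0.0 and r.confusion[1].sum() == 0.0

    def test_accuracy_equals_confusion_trace_identity(self, rng):
        y_true = rng.integers(0, 3, size=200)
        y_pred = rng.integers(0, 3, size=200)
        r = compute_metrics(y_true, y_pred)
        assert r.accuracy == pytest.approx(np.trace(r.confusion_counts) / 200)
        assert r.weighted_f1 <= 1.0


class TestTrainSettings:
    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError):
            TrainSettings(max_epochs=10, patience=10)

    def test_positive_learning_rate(self):
        with pytest.raises(ValueError):
            TrainSettings(learning_rate=0.0)


class TestTrainModel:
    def test_early_stop_contract_on_constant_data(self):
        """With patience 1 and constant data the loop stops within two
        epochs of the first (no validation improvement is possible)."""
        model = build_fcn(TINY, seed=0)
        X = np.ones((12, 50))
        y = np.tile([0, 1, 2], 4)
        settings = TrainSettings(max_epochs=50, patience=1, seed=0)
        hist = train_model(model, X, y, X.copy(), y.copy(), settings)
        assert len(hist.records) <= 3

    def test_identical_runs_identical_history(self):
        ws = synthetic_windowset(n_subjects=4, seed=5)
        X, y, subj = ws.matrix()

        def run():
            model = build_fcn(TINY, seed=3)
            settings = TrainSettings(max_epochs=5, patience=4, seed=8)
            return train_model(model, X[:24], y[:24], X[24:], y[24:], settings), model

        h1, m1 = run()
        h2, m2 = run()
        assert h1.as_rows() == h2.as_rows()
        for a, b in zip(m1.net.state(), m2.net.state()):
            assert np.array_equal(a, b)

    def test_returns_best_checkpoint(self):
        """The retained parameters reproduce the best recorded validation
        accuracy, never a later, worse epoch."""
        ws = synthetic_windowset(n_subjects=6, seed=2)
        X, y, subj = ws.matrix()
        tr = np.isin(subj, [f"P{i:02d}" for i in range(4)])
        model = build_fcn(TINY, seed=1)
        settings = TrainSettings(max_epochs=15, patience=14, seed=0)
        hist = train_model(model, X[tr], y[tr], X[~tr], y[~tr], settings,
                           train_subjects=subj[tr], val_subjects=subj[~tr])
        assert hist.best_val_accuracy == max(r.val_accuracy for r in hist.records)
        assert evalcv._accuracy(model, X[~tr], y[~tr]) == pytest.approx(hist.best_val_accuracy)

    def test_separable_toy_data_learns(self):
        ws = synthetic_windowset(n_subjects=8, sep=3.0, seed=7)
        X, y, subj = ws.matrix()
        tr = np.isin(subj, [f"P{i:02d}" for i in range(6)])
        model = build_fcn(TINY, seed=4)
        settings = TrainSettings(max_epochs=60, patience=59, learning_rate=3e-3, seed=1)
        hist = train_model(model, X[tr], y[tr], X[~tr], y[~tr], settings)
        assert hist.best_val_accuracy > 0.8

    def test_subject_overlap_rejected(self):
        model = build_fcn(TINY, seed=0)
        X = np.ones((6, 50))
        y = np.array([0, 1, 2, 0, 1, 2])
        with pytest.raises(LeakageError):
            train_model(model, X, y, X, y, TrainSettings(max_epochs=5, patience=1),
                        train_subjects=["a"] * 6, val_subjects=["a"] * 6)

    def test_empty_split_rejected(self):
        model = build_fcn(TINY, seed=0)
        with pytest.raises(ValueError):
            train_model(model, np.empty((0, 50)), np.empty(0, int), np.ones((2, 50)),
                        np.array([0, 1]), TrainSettings(max_epochs=5, patience=1))


@pytest.fixture(scope="module")
def cv_result():
    ws = synthetic_windowset(n_subjects=10, sep=4.0, seed=3)
    folds = assign_folds(ws.subject_ids(), k=5, seed=0)
    settings = TrainSettings(max_epochs=50, patience=49, learning_rate=5e-3, seed=0)
    return cross_validate(ws, lambda f: build_fcn(TINY, seed=f), folds, settings)


class TestCrossValidate:
    def test_five_reports_with_provenance(self, cv_result):
        assert [f.fold for f in cv_result.folds] == [1, 2, 3, 4, 5]
        for f in cv_result.folds:
            assert f.report.provenance["fold"] == f.fold
            assert f.report.provenance["n_test_subjects"] == 2

    def test_median_fold_is_the_middle_accuracy(self, cv_result):
        accs = sorted(cv_result.accuracies)
        assert cv_result.median_result.report.accuracy == accs[2]

    def test_mean_accuracy_beats_chance_on_separable_data(self, cv_result):
        assert cv_result.mean_accuracy > 0.8

    def test_median_tie_breaks_to_lowest_fold_index(self):
        from edapain.evalcv import FoldResult, _median_fold

        def fake(fold, acc):
            r = compute_metrics(np.array([0, 1]), np.array([0, 1] if acc else [1, 0]))
            return FoldResult(fold=fold, report=r, history=None, model=None)

        results = [fake(f, True) for f in range(1, 6)]  # all identical
        assert _median_fold(results) == 1
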