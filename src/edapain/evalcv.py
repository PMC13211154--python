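"""Subject-wise cross-validation, FCN training, and evaluation.

The protocol: subjects (never windows) are randomly partitioned into k
near-equal folds; in CV iteration i, fold i is the test set, fold
(i mod k)+1 the validation set, and the remaining k−2 folds the training
set.  Training uses Adam on cross-entropy with early stopping on
validation accuracy and a reduce-on-plateau learning-rate schedule; the
checkpoint with the highest validation accuracy is retained.  The
reported summary is the mean ± sd over folds plus the median-performing
fold (by test accuracy, ties to the lowest fold index).

A leakage guard asserts at runtime that the train/validation/test
subject sets of every fold are pairwise disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from edapain import nn
from edapain.fcn import FcnModel, predict_with_confidence
from edapain.metrics import MetricsReport, compute_metrics
from edapain.preprocess import WindowSet


class LeakageError(RuntimeError):
    """Overlapping subject sets between CV splits."""


@dataclass(frozen=True)
class TrainSettings:
    """Optimisation settings for the FCN.

    Defaults mirror the full offline protocol (Adam, lr ≈ 1.94e−4,
    up to 3000 epochs, early-stopping patience 500 epochs on validation
    accuracy, reduce-on-plateau scheduling); reduced-budget runs override
    ``max_epochs``/``patience``.
    """

    max_epochs: int = 3000
    patience: int = 500
    learning_rate: float = 1.94e-4
    scheduler_factor: float = 0.5
    scheduler_patience: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FoldAssignment:
    """subject_id → fold index in 1..k."""

    mapping: dict[str, int]
    k: int

    def subjects_in(self, fold: int) -> list[str]:
        return [s for s, f in self.mapping.items() if f == fold]


def assign_folds(subject_ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded random permutation chunked into k near-equal folds."""
    subject_ids = list(subject_ids)
    if len(subject_ids) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(subject_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    chunks = np.array_split(order, k)
    mapping = {}
    for fold, chunk in enumerate(chunks, start=1):
        for idx in chunk:
            mapping[subject_ids[idx]] = fold
    return FoldAssignment(mapping=mapping, k=k)


def check_disjoint(**named_subject_sets: set[str]) -> None:
    names = list(named_subject_sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = named_subject_sets[a] & named_subject_sets[b]
            if overlap:
                raise LeakageError(f"subject sets {a} and {b} overlap: {sorted(overlap)[:5]}")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float
    learning_rate: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -np.inf

    def as_rows(self) -> list[tuple]:
        return [(r.epoch, r.train_loss, r.val_accuracy, r.learning_rate) for r in self.records]


def _accuracy(model: FcnModel, X: np.ndarray, y: np.ndarray) -> float:
    classes, _ = predict_with_confidence(model.predict_logits(X))
    return float((classes == y).mean())


def train_model(
    model: FcnModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    settings: TrainSettings,
    train_subjects: Sequence[str] | None = None,
    val_subjects: Sequence[str] | None = None,
) -> TrainHistory:
    """Train in place; on return the model holds the parameters of the
    best-validation-accuracy epoch."""
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("empty train or validation split")
    if train_subjects is not None and val_subjects is not None:
        check_disjoint(train=set(train_subjects), val=set(val_subjects))

    rng = np.random.default_rng(settings.seed)
    opt = nn.Adam(model.net, lr=settings.learning_rate)
    history = TrainHistory()
    best_state = model.net.state()
    since_improve = 0
    since_lr_improve = 0
    n = len(X_train)

    for epoch in range(settings.max_epochs):
        for layer in model.net.layers:  # fresh inference stats per epoch
            if isinstance(layer, nn.BatchNorm1d):
                layer.reset_epoch_stats()
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, settings.batch_size):
            idx = perm[i : i + settings.batch_size]
            logits = model.forward(X_train[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(model, X_val, y_val)
        history.records.append(EpochRecord(epoch, float(np.mean(losses)), val_acc, opt.lr))

        if val_acc > history.best_val_accuracy:
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_state = model.net.state()
            since_improve = 0
            since_lr_improve = 0
        else:
            since_improve += 1
            since_lr_improve += 1
        if since_lr_improve >= settings.scheduler_patience:
            opt.lr *= settings.scheduler_factor  # reduce-on-plateau
            since_lr_improve = 0
        if since_improve >= settings.patience:
            break

    model.net.load_state(best_state)
    return history


def evaluate(model, X: np.ndarray, y: np.ndarray, provenance: dict | None = None) -> MetricsReport:
    """Score an FCN (via logits) or any sklearn-style classifier (via
    ``predict``) on a test set."""
    if len(X) == 0:
        raise ValueError("empty test set")
    if isinstance(model, FcnModel):
        y_pred, _ = predict_with_confidence(model.predict_logits(X))
    elif hasattr(model, "predict"):
        y_pred = np.asarray(model.predict(X))
    else:
        raise TypeError("model must be an FcnModel or expose .predict")
    return compute_metrics(y, y_pred, provenance=provenance)


@dataclass
class FoldResult:
    fold: int
    report: MetricsReport
    history: TrainHistory
    model: FcnModel


@dataclass
class CvResult:
    folds: list[FoldResult]
    median_fold: int

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.report.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.folds) > 1 else 0.0

    @property
    def median_result(self) -> FoldResult:
        return next(f for f in self.folds if f.fold == self.median_fold)


def fold_split(folds: FoldAssignment, test_fold: int) -> tuple[set[str], set[str], set[str]]:
    """(train, val, test) subject sets for one CV iteration; validation is
    fold (test mod k)+1, training the remaining k−2 folds."""
    k = folds.k
    val_fold = (test_fold % k) + 1
    test = set(folds.subjects_in(test_fold))
    val = set(folds.subjects_in(val_fold))
    train = {s for s, f in folds.mapping.items() if f not in (test_fold, val_fold)}
    check_disjoint(train=train, val=val, test=test)
    return train, val, test


def _median_fold(results: list[FoldResult]) -> int:
    accs = sorted(r.report.accuracy for r in results)
    median_acc = accs[(len(accs) - 1) // 2]  # lower middle for even counts
    return min(r.fold for r in results if r.report.accuracy == median_acc)


def cross_validate(
    dataset: WindowSet,
    model_factory: Callable[[int], FcnModel],
    folds: FoldAssignment,
    settings: TrainSettings,
) -> CvResult:
    """Run all k subject-wise CV iterations of the FCN."""
    X, y, subjects = dataset.matrix()
    results = []
    for test_fold in range(1, folds.k + 1):
        train_s, val_s, test_s = fold_split(folds, test_fold)
        tr = np.isin(subjects, sorted(train_s))
        va = np.isin(subjects, sorted(val_s))
        te = np.isin(subjects, sorted(test_s))
        model = model_factory(test_fold)
        fold_settings = TrainSettings(**{**settings.__dict__, "seed": settings.seed + test_fold})
        history = train_model(
            model, X[tr], y[tr], X[va], y[va], fold_settings,
            train_subjects=subjects[tr], val_subjects=subjects[va],
        )
        report = evaluate(model, X[te], y[te], provenance={"fold": test_fold, "n_test_subjects": len(test_s)})
        results.append(FoldResult(fold=test_fold, report=report, history=history, model=model))
    return CvResult(folds=results, median_fold=_median_fold(results))
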