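"""Classical reference classifiers with fixed, pre-selected hyperparameters.

Five models — LDA, logistic regression, a polynomial-kernel SVM,
AdaBoost, and gradient boosting — act as feature-based reference points
for the FCN.  Their hyperparameters are configuration, not searched:
LDA uses the SVD solver; LR an l2 penalty with C = 97.2 under the
Newton–Cholesky solver (the recorded l1 ratio of 0.07 is inert under a
pure l2 penalty and kept only for provenance); the SVM a degree-4
polynomial kernel with 'auto' kernel coefficient; AdaBoost 227
estimators at learning rate 0.78; GBoost 438 estimators at learning
rate 0.52 with the squared-error criterion.

This module is deliberately thin over scikit-learn: the substance here
is the configuration and the subject-disjoint evaluation contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from edapain.evalcv import check_disjoint, evaluate
from edapain.metrics import MetricsReport

MODEL_NAMES = ("LDA", "LR", "SVM", "AdaBoost", "GBoost")

#: the fixed selected hyperparameters, one schema per model
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LDA": {"solver": "svd"},
    "LR": {"penalty": "l2", "C": 97.2, "solver": "newton-cholesky", "l1_ratio": 0.07},
    "SVM": {"kernel": "poly", "degree": 4, "gamma": "auto"},
    "AdaBoost": {"n_estimators": 227, "learning_rate": 0.78},
    "GBoost": {"n_estimators": 438, "learning_rate": 0.52, "criterion": "squared_error"},
}

_VALID_KEYS = {name: set(params) for name, params in DEFAULT_HYPERPARAMETERS.items()}
_VALID_CHOICES = {
    ("LDA", "solver"): {"svd", "lsqr", "eigen"},
    ("LR", "penalty"): {"l1", "l2", "elasticnet", None},
    ("LR", "solver"): {"lbfgs", "newton-cg", "newton-cholesky", "sag", "saga"},
    ("SVM", "kernel"): {"linear", "poly", "rbf"},
    ("GBoost", "criterion"): {"friedman_mse", "squared_error"},
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigurationError(f"unknown model {self.name!r}; valid names: {MODEL_NAMES}")
        unknown = set(self.hyperparameters) - _VALID_KEYS[self.name]
        if unknown:
            raise ConfigurationError(
                f"{self.name}: unknown hyperparameters {sorted(unknown)}; valid: {sorted(_VALID_KEYS[self.name])}"
            )
        for key, value in self.hyperparameters.items():
            choices = _VALID_CHOICES.get((self.name, key))
            if choices is not None and value not in choices:
                raise ConfigurationError(f"{self.name}.{key}={value!r} invalid; valid options: {sorted(map(str, choices))}")

    def resolved(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.name], **self.hyperparameters}


def default_specs(seed: int = 0) -> list[BaselineSpec]:
    return [BaselineSpec(name, seed=seed) for name in MODEL_NAMES]


def make_baseline(spec: BaselineSpec):
    """Instantiate the scikit-learn estimator for a validated spec.

    The returned handle exposes ``fit``/``predict`` and, where the model
    defines class probabilities, ``predict_proba``.  The SVM predicts via
    the decision-function argmax (no probability calibration).
    """
    hp = spec.resolved()
    if spec.name == "LDA":
        return LinearDiscriminantAnalysis(solver=hp["solver"])
    if spec.name == "LR":
        # l1_ratio is recorded configuration but inert under the l2 penalty
        return LogisticRegression(penalty=hp["penalty"], C=hp["C"], solver=hp["solver"], max_iter=5000)
    if spec.name == "SVM":
        return SVC(kernel=hp["kernel"], degree=hp["degree"], gamma=hp["gamma"], random_state=spec.seed)
    if spec.name == "AdaBoost":
        return AdaBoostClassifier(n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"], random_state=spec.seed)
    if spec.name == "GBoost":
        return GradientBoostingClassifier(
            n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
            criterion=hp["criterion"], random_state=spec.seed,
        )
    raise ConfigurationError(f"unknown model {spec.name!r}")  # pragma: no cover - guarded in spec


def train_and_eval_baseline(
    spec: BaselineSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    train_subjects: Sequence[str] | None = None,
    test_subjects: Sequence[str] | None = None,
) -> MetricsReport:
    """Fit on the training features, score on the test features.

    If subject identifiers are provided, train/test disjointness is
    enforced before any fitting happens.
    """
    if train_subjects is not None and test_subjects is not None:
        check_disjoint(train=set(train_subjects), test=set(test_subjects))
    clf = make_baseline(spec)
    clf.fit(X_train, y_train)
    return evaluate(clf, X_test, y_test, provenance={"model": spec.name})
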