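"""Condition classification from system-level nonreversibility features.

Each (participant, condition) contributes one feature vector — typically
the per-network mean R (seven features for a Yeo-7 atlas) — and the class
label is the condition.  Classification uses a one-vs-one ensemble of
Gaussian-kernel (RBF) support vector machines, K(K-1)/2 binary models for
K classes, with per-feature standardization fit on the training fold only.
Performance is summarized by a confusion matrix averaged over repeated
stratified 90/10 splits, and chance level is estimated by label
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def n_binary_classifiers(n_classes: int) -> int:
    """Number of one-vs-one binary SVMs: K(K-1)/2."""
    return n_classes * (n_classes - 1) // 2


def _validate(features, labels):
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D and align with labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with fewer than 2 rows: {small.tolist()}")
    return X, y, classes


def train_condition_svm(features, labels, seed: int = 0, C: float = 1.0,
                        gamma="scale") -> Pipeline:
    """Fit the standardize + one-vs-one RBF-SVM pipeline.

    The RBF kernel scale ``gamma`` and box constraint ``C`` default to
    scikit-learn's conventions ('scale' and 1.0); both are exposed since no
    canonical values exist for this feature family.  Deterministic under
    ``seed``.
    """
    X, y, _ = _validate(features, labels)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=C, gamma=gamma,
                    decision_function_shape="ovo",
                    random_state=seed)),
    ])
    return model.fit(X, y)


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion proportions averaged over repeated splits."""

    proportions: np.ndarray
    classes: list
    n_repeats: int
    per_repeat_accuracy: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def mean_diagonal(self) -> float:
        """Mean of the diagonal of the averaged proportion matrix."""
        return float(np.mean(np.diag(self.proportions)))

    @property
    def mean_repeat_accuracy(self) -> float:
        """Average per-repeat overall accuracy (alternative summary)."""
        return float(np.mean(self.per_repeat_accuracy))


def evaluate_confusion(features, labels, eval_fraction: float = 0.1,
                       n_repeats: int = 100, seed: int = 0, C: float = 1.0,
                       gamma="scale") -> ConfusionMatrix:
    """Repeated stratified hold-out evaluation of the condition SVM.

    The rows are split ``n_repeats`` times into (1 - eval_fraction) train
    and ``eval_fraction`` evaluation parts, stratified by class so every
    class appears in every fold.  Each repeat's row-normalized confusion
    matrix is averaged; rows of the result sum to 1.
    """
    X, y, classes = _validate(features, labels)
    splitter = StratifiedShuffleSplit(n_splits=n_repeats,
                                      test_size=eval_fraction,
                                      random_state=seed)
    acc = np.empty(n_repeats)
    total = np.zeros((len(classes), len(classes)))
    for rep, (tr, te) in enumerate(splitter.split(X, y)):
        model = train_condition_svm(X[tr], y[tr], seed=seed, C=C, gamma=gamma)
        pred = model.predict(X[te])
        cm = _sk_confusion(y[te], pred, labels=classes, normalize="true")
        total += cm
        acc[rep] = float(np.mean(pred == y[te]))
    return ConfusionMatrix(total / n_repeats, list(classes), n_repeats, acc)


@dataclass
class PermutationNull:
    """Null distribution of the mean confusion diagonal under label shuffling."""

    null_accuracies: np.ndarray
    null_mean: float
    ci_low: float
    ci_high: float
    observed: float | None = None
    p_value: float | None = None


def permutation_chance(features, labels, n_perms: int = 100, seed: int = 0,
                       n_repeats: int = 20, eval_fraction: float = 0.1,
                       observed_accuracy: float | None = None,
                       C: float = 1.0, gamma="scale") -> PermutationNull:
    """Estimate chance-level accuracy by permuting condition labels.

    For each of ``n_perms`` permutations the labels are shuffled across
    rows, the repeated-split evaluation rerun, and the mean confusion
    diagonal recorded.  Returns the null mean, a 95% percentile interval,
    and — when ``observed_accuracy`` is given — the empirical p-value
    (#{null >= observed} + 1)/(n_perms + 1).
    """
    if n_perms < 20:
        raise ValueError("n_perms must be >= 20 for a usable null")
    X, y, _ = _validate(features, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perms)
    for k in range(n_perms):
        y_perm = y[rng.permutation(len(y))]
        cm = evaluate_confusion(X, y_perm, eval_fraction=eval_fraction,
                                n_repeats=n_repeats,
                                seed=int(rng.integers(2 ** 31)),
                                C=C, gamma=gamma)
        null[k] = cm.mean_diagonal
    ci_low, ci_high = np.percentile(null, [2.5, 97.5])
    p = None
    if observed_accuracy is not None:
        p = float((np.sum(null >= observed_accuracy) + 1) / (n_perms + 1))
    return PermutationNull(null, float(null.mean()), float(ci_low),
                           float(ci_high), observed_accuracy, p)


def rest_vs_all(labels, rest_label: str):
    """Collapse condition labels to a binary rest-vs-task coding."""
    y = np.asarray(labels)
    if rest_label not in set(y.tolist()):
        raise ValueError(f"label {rest_label!r} not present")
    return np.where(y == rest_label, rest_label, "other")
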