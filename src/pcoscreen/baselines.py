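"""Comparison classifiers on the ordinal-encoded questionnaire.

The baseline track mirrors a conventional tabular pipeline: a stratified
80/20 train/test split, nearest-neighbour mean oversampling of minority
classes on the training partition only, and one of three classifiers
(RBF-kernel SVM, k-nearest neighbours, decision tree) fit on the balanced
training data.

The oversampler equalises every class count to the majority count by
adding, per synthetic row, the arithmetic mean of a randomly drawn
minority sample and its k within-class Euclidean nearest neighbours;
original rows are never removed or altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODELS = ("svm", "knn", "dtree")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test partition parameters."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class BalancerSpec:
    """Nearest-neighbour mean oversampling parameters."""

    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")


def stratified_split(matrix, labels, spec: SplitSpec = SplitSpec()):
    """Split into train/test preserving class proportions.

    Returns ``(X_train, X_test, y_train, y_test, idx_train, idx_test)``.
    """
    matrix = np.asarray(matrix)
    labels = np.asarray(labels)
    if matrix.shape[0] != labels.shape[0]:
        raise ValueError("matrix and labels must have equal length")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        lonely = classes[counts < 2].tolist()
        raise ValueError(f"classes with a single sample cannot be split: {lonely}")
    idx = np.arange(matrix.shape[0])
    idx_train, idx_test = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratified else None,
        shuffle=True,
    )
    return (
        matrix[idx_train],
        matrix[idx_test],
        labels[idx_train],
        labels[idx_test],
        idx_train,
        idx_test,
    )


def knn_balance(matrix, labels, spec: BalancerSpec = BalancerSpec()):
    """Oversample minority classes to the majority count with KNN means.

    Each synthetic row is the mean of one randomly chosen class member and
    its k nearest neighbours within the same class (k clamped to class
    size − 1 when the class is smaller than k + 1).  Originals are kept
    untouched; already-balanced input is returned unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    new_rows, new_labels = [matrix], [labels]
    for cls, count in zip(classes, counts):
        deficit = int(target - count)
        if deficit == 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls!r} has a single member; cannot synthesise neighbours")
        members = matrix[labels == cls]
        k = min(spec.k, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(members)  # +1: the anchor itself
        _, neigh = nn.kneighbors(members)
        anchors = rng.integers(0, count, size=deficit)
        synth = np.stack([members[neigh[a]].mean(axis=0) for a in anchors])
        new_rows.append(synth)
        new_labels.append(np.full(deficit, cls, dtype=labels.dtype))
    return np.concatenate(new_rows), np.concatenate(new_labels)


def make_model(model: str, seed: int = 0, **hyperparams):
    """Instantiate one of the baseline classifiers by name."""
    if model == "svm":
        return SVC(kernel=hyperparams.pop("kernel", "rbf"), random_state=seed, **hyperparams)
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=hyperparams.pop("n_neighbors", 5), **hyperparams)
    if model == "dtree":
        return DecisionTreeClassifier(random_state=seed, **hyperparams)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def train_and_predict(X_train, y_train, X_test, model: str = "svm", seed: int = 0, **hyperparams):
    """Fit the named classifier on the training partition and predict the test rows."""
    clf = make_model(model, seed=seed, **hyperparams)
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return clf.predict(np.asarray(X_test, dtype=float))
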