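"""Classifiers over global vectors and confusion-matrix reporting.

k-NN uses the Manhattan (L1) distance.  Ties in the neighbour vote are
broken deterministically: among tied labels, the label whose nearest
member is closest wins; residual ties fall back to lexicographic label
order.  The SVM is scikit-learn's max-margin classifier (one-vs-one for
multiclass), linear kernel by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn import svm as _svm

from .errors import ValidationError

__all__ = [
    "LabeledSet",
    "ConfusionMatrix",
    "knn_predict",
    "svm_train_predict",
    "confusion",
]


@dataclass
class LabeledSet:
    """``(n x r)`` vectors with one class label per row."""

    vectors: np.ndarray
    labels: list[str]
    provenance: list | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.labels = list(self.labels)
        if self.vectors.shape[0] != len(self.labels):
            raise ValidationError("one label per vector required")
        if self.vectors.shape[0] < 1:
            raise ValidationError("labeled set may not be empty")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ConfusionMatrix:
    """Counts of true class (rows) vs predicted class (columns)."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))

    def as_percentages(self) -> pd.DataFrame:
        """Row-normalized percentages (each true class sums to 100)."""
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        row_sums[row_sums == 0] = 1.0
        return pd.DataFrame(100.0 * self.counts / row_sums,
                            index=list(self.class_order),
                            columns=list(self.class_order))


def knn_predict(train: LabeledSet, test_vectors, k: int = 1,
                metric: str = "manhattan") -> list[str]:
    """Majority vote among the ``k`` nearest training vectors (L1 metric)."""
    if metric != "manhattan":
        raise ValidationError(f"unsupported metric {metric!r}")
    if not 1 <= k <= train.n:
        raise ValidationError(f"need 1 <= k <= n_train={train.n}, got {k}")
    test = np.atleast_2d(np.asarray(test_vectors, dtype=float))
    dist = cdist(test, train.vectors, metric="cityblock")
    labels = np.asarray(train.labels, dtype=object)
    out = []
    for row in dist:
        # stable order: by distance, then training index
        order = np.lexsort((np.arange(train.n), row))
        nearest = order[:k]
        votes = Counter(labels[nearest])
        top = max(votes.values())
        tied = [lab for lab, n in votes.items() if n == top]
        if len(tied) > 1:
            # closest member wins; then lexicographic label order
            best_d = {lab: min(row[i] for i in nearest if labels[i] == lab)
                      for lab in tied}
            tied.sort(key=lambda lab: (best_d[lab], lab))
        out.append(tied[0])
    return out


def svm_train_predict(train: LabeledSet, test_vectors,
                      kernel: str = "linear",
                      regularization: float = 1.0) -> list[str]:
    """Fit a support-vector machine on the training set and predict.

    Multiclass problems use one-vs-one voting.  Deterministic for fixed
    inputs.
    """
    if len(set(train.labels)) < 2:
        raise ValidationError("SVM needs >= 2 classes in the training set")
    test = np.atleast_2d(np.asarray(test_vectors, dtype=float))
    clf = _svm.SVC(kernel=kernel, C=regularization)
    clf.fit(train.vectors, train.labels)
    return list(clf.predict(test))


def confusion(true_labels, predicted, class_order) -> ConfusionMatrix:
    """Count table of (true, predicted) pairs in ``class_order``."""
    true_labels, predicted = list(true_labels), list(predicted)
    if len(true_labels) != len(predicted):
        raise ValidationError("label sequences differ in length")
    class_order = tuple(class_order)
    index = {lab: i for i, lab in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted):
        if t not in index or p not in index:
            raise ValidationError(
                f"label outside class order: true={t!r} pred={p!r}"
            )
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)
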