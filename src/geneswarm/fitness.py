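"""The wrapper objective: SVM leave-one-out accuracy plus a subset-size bonus.

A candidate subset (the 1-bits of a particle) is scored by

    score = accuracy_weight * LOOCV_accuracy_percent
          + size_weight * reference_size / feature_number

with weights 0.6 / 0.4 and reference size 50, so accuracy dominates and,
among equally accurate subsets, smaller ones win.  Accuracy enters on the
percent scale (0-100): on the 0-1 scale the size term (up to 50 for a
singleton subset) would swamp the accuracy term and the search would
collapse onto one-gene subsets regardless of their accuracy.

The classifier is a C-SVC with an RBF kernel at libsvm defaults (C = 1,
gamma = 1 / n_selected_features).  For speed the leave-one-out loop calls
scikit-learn's low-level libsvm bindings directly; the predictions are
identical to fitting an ``sklearn.svm.SVC`` per fold (the ``backend="svc"``
route, kept for cross-checking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .binary_core import Bits, as_bits
from .dataset import LabeledExpressionDataset

try:  # low-level libsvm entry points (same solver SVC wraps)
    from sklearn.svm import _libsvm as _llsvm

    _llsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _llsvm = None

from sklearn.svm import SVC

__all__ = [
    "FitnessWeights",
    "SVMConfig",
    "FitnessValue",
    "SENTINEL_SCORE",
    "loocv_accuracy",
    "subset_fitness",
    "evaluate_particle",
    "make_evaluator",
]

#: Score assigned to the empty subset: never beats any non-empty subset.
SENTINEL_SCORE = -math.inf


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the accuracy and size terms of the composite score."""

    accuracy_weight: float = 0.6
    size_weight: float = 0.4
    reference_size: int = 50


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel C-SVC settings.

    ``gamma="auto"`` applies the libsvm default rule 1 / n_selected_features;
    a positive float fixes gamma explicitly.  ``backend`` selects the fast
    low-level libsvm route or per-fold ``SVC`` objects (identical results).
    """

    cost_c: float = 1.0
    gamma: float | str = "auto"
    backend: str = "libsvm"

    def gamma_value(self, n_features: int) -> float:
        if self.gamma == "auto":
            return 1.0 / n_features
        g = float(self.gamma)
        if g <= 0:
            raise ValueError("gamma must be positive")
        return g


@dataclass(frozen=True)
class FitnessValue:
    """LOOCV accuracy (percent), subset size, and the composite score."""

    accuracy: float
    feature_number: int
    score: float


def _loocv_low_level(X: np.ndarray, y: np.ndarray, c: float, gamma: float) -> float:
    n = X.shape[0]
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        ytr = y[mask]
        if ytr[0] == ytr[-1] and (ytr == ytr[0]).all():
            pred = ytr[0]
        else:
            model = _llsvm.fit(
                np.ascontiguousarray(X[mask]), ytr,
                svm_type=0, kernel="rbf", C=c, gamma=gamma,
            )
            pred = _llsvm.predict(
                X[i : i + 1], *model[:5], svm_type=0, kernel="rbf", gamma=gamma
            )[0]
        correct += pred == y[i]
        mask[i] = True
    return 100.0 * correct / n


def _loocv_svc(X: np.ndarray, y: np.ndarray, c: float, gamma: float) -> float:
    n = X.shape[0]
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        ytr = y[mask]
        if (ytr == ytr[0]).all():
            pred = ytr[0]
        else:
            pred = SVC(C=c, gamma=gamma).fit(X[mask], ytr).predict(X[i : i + 1])[0]
        correct += pred == y[i]
        mask[i] = True
    return 100.0 * correct / n


def loocv_accuracy(data: LabeledExpressionDataset, config: SVMConfig = SVMConfig()) -> float:
    """Leave-one-out cross-validated accuracy, in percent.

    Trains n independent SVMs, each on n-1 samples, and predicts the held-out
    sample; deterministic given the data and configuration.  A training fold
    that contains a single class (possible when one class has a single
    sample) predicts that sole class.
    """
    if data.n_samples < 2:
        raise ValueError("LOOCV needs at least two samples")
    if data.n_genes < 1:
        raise ValueError("at least one gene must be selected")
    X = np.ascontiguousarray(data.matrix.T, dtype=np.float64)  # samples x genes
    _, y = np.unique(data.labels, return_inverse=True)
    y = y.astype(np.float64)
    gamma = config.gamma_value(data.n_genes)
    if config.backend == "libsvm" and _llsvm is not None:
        return _loocv_low_level(X, y, config.cost_c, gamma)
    if config.backend in ("libsvm", "svc"):
        return _loocv_svc(X, y, config.cost_c, gamma)
    raise ValueError(f"unknown SVM backend: {config.backend!r}")


def subset_fitness(
    accuracy: float, feature_number: int, weights: FitnessWeights = FitnessWeights()
) -> float:
    """Composite score of a non-empty subset (accuracy in percent)."""
    if feature_number < 1:
        raise ValueError("feature_number must be at least 1")
    if not 0.0 <= accuracy <= 100.0:
        raise ValueError("accuracy must lie in [0, 100]")
    return (
        weights.accuracy_weight * accuracy
        + weights.size_weight * weights.reference_size / feature_number
    )


def evaluate_particle(
    position: str | Bits,
    data: LabeledExpressionDataset,
    weights: FitnessWeights = FitnessWeights(),
    config: SVMConfig = SVMConfig(),
) -> FitnessValue:
    """Score one particle: LOOCV accuracy on its 1-bit genes plus size bonus.

    The all-zero position gets the sentinel score (-inf) with accuracy
    recorded as 0, so it is never preferred over any non-empty subset.
    """
    bits = as_bits(position)
    if bits.shape[0] != data.n_genes:
        raise ValueError(
            f"position length {bits.shape[0]} does not match gene count {data.n_genes}"
        )
    k = int(bits.sum())
    if k == 0:
        return FitnessValue(accuracy=0.0, feature_number=0, score=SENTINEL_SCORE)
    rows = np.flatnonzero(bits)
    sub = LabeledExpressionDataset(
        matrix=data.matrix[rows],
        gene_ids=[data.gene_ids[i] for i in rows],
        labels=data.labels,
        sample_ids=list(data.sample_ids),
    )
    acc = loocv_accuracy(sub, config)
    return FitnessValue(
        accuracy=acc, feature_number=k, score=subset_fitness(acc, k, weights)
    )


def make_evaluator(
    data: LabeledExpressionDataset,
    weights: FitnessWeights = FitnessWeights(),
    config: SVMConfig = SVMConfig(),
) -> Callable[[Bits], FitnessValue]:
    """A cached particle evaluator for the optimizer loops.

    The SVM fit is deterministic, so results are memoised by position; the
    optimizer's evaluation count stays exactly interpretable while repeated
    visits to the same subset cost nothing.
    """
    cache: dict[bytes, FitnessValue] = {}

    def evaluator(position: Bits) -> FitnessValue:
        key = as_bits(position).tobytes()
        hit = cache.get(key)
        if hit is None:
            hit = cache[key] = evaluate_particle(position, data, weights, config)
        return hit

    return evaluator
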