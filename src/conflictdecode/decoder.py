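"""Decoding kernel: shrinkage LDA, class-balanced k-fold partitions, accuracy.

Every analysis in the package reduces to this module: build a
class-balanced :class:`FoldPartition` once per subject, then score feature
matrices with :func:`cv_accuracy`.  The classifier is a two-class linear
discriminant with the pooled within-class covariance shrunk toward a
scaled identity,

    S' = (1 - lam) * S + lam * (trace(S) / p) * I,
    w  = S'^{-1} (mu1 - mu0),      b = -w . (mu0 + mu1) / 2,

predicting class 1 when ``w . x + b > 0``.  Ties (decision value exactly
zero) go to class 0, a documented reproducibility convention.  Chance
level for balanced two-class data is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["FoldPartition", "LdaModel", "balanced_partition", "fit_lda",
           "cv_accuracy", "CHANCE_LEVEL"]

CHANCE_LEVEL = 0.5


@dataclass(frozen=True)
class FoldPartition:
    """Balanced stratified folds, possibly over several balancing repeats.

    ``folds[r]`` is the list of ``(train_idx, test_idx)`` pairs of repeat
    ``r``; indices refer to rows of the feature matrix the partition was
    built for.  Within a repeat the test sets are disjoint and every fold
    is class-balanced in both its train and test part.
    """

    k: int
    n_repeats: int
    seed: int
    folds: tuple[tuple[tuple[np.ndarray, np.ndarray], ...], ...]

    def __iter__(self):
        for repeat in self.folds:
            yield from repeat


def balanced_partition(labels: np.ndarray, k: int = 10, n_repeats: int = 1,
                       seed: int = 0) -> FoldPartition:
    """Stratified k-fold assignment after subsampling the majority class.

    Per repeat, the majority class is subsampled without replacement to
    the minority count; the balanced trials are then dealt into ``k``
    folds class by class, so every fold's train and test sets hold equal
    numbers of both classes.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])
    m = min(idx0.size, idx1.size)
    if m < k:
        raise ValueError(
            f"minority class has {m} trials < k={k} folds; use a smaller k")
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        sub0 = rng.choice(idx0, size=m, replace=False) if idx0.size > m else idx0.copy()
        sub1 = rng.choice(idx1, size=m, replace=False) if idx1.size > m else idx1.copy()
        rng.shuffle(sub0)
        rng.shuffle(sub1)
        # drop the remainder so every fold is exactly balanced
        per_fold = m // k
        folds = []
        used0 = sub0[: per_fold * k]
        used1 = sub1[: per_fold * k]
        for f in range(k):
            test = np.sort(np.concatenate([
                used0[f * per_fold:(f + 1) * per_fold],
                used1[f * per_fold:(f + 1) * per_fold]]))
            train = np.sort(np.concatenate([
                np.delete(used0, slice(f * per_fold, (f + 1) * per_fold)),
                np.delete(used1, slice(f * per_fold, (f + 1) * per_fold))]))
            folds.append((train, test))
        repeats.append(tuple(folds))
    return FoldPartition(k=k, n_repeats=n_repeats, seed=seed, folds=tuple(repeats))


@dataclass(frozen=True)
class LdaModel:
    """Fitted two-class shrinkage discriminant."""

    weights: np.ndarray
    bias: float
    lam: float
    classes: tuple
    chance_level: float = CHANCE_LEVEL

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties (decision value == 0) go to class 0
        d = self.decision_values(X)
        return np.where(d > 0, self.classes[1], self.classes[0])


def fit_lda(X: np.ndarray, y: np.ndarray, lam: float = 0.01) -> LdaModel:
    """Fit the shrinkage LDA on training rows ``X`` with labels ``y``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if not 0 <= lam <= 1:
        raise ValueError(f"shrinkage lam must be in [0, 1], got {lam}")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fit_lda requires exactly two classes in y")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need at least two training trials per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n, p = X.shape
    # pooled within-class scatter, unbiased (n - 2 df); shrinkage is
    # invariant to this normalization because both terms are linear in S
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n - 2)
    S = (1 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    try:
        cho = linalg.cho_factor(S, lower=True)
        w = linalg.cho_solve(cho, mu1 - mu0)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular (likely lam=0 with more "
            "features than trials); use lam > 0") from err
    bias = -float(w @ (mu0 + mu1) / 2)
    return LdaModel(weights=w, bias=bias, lam=lam,
                    classes=(classes[0], classes[1]))


def cv_accuracy(X: np.ndarray, y: np.ndarray, partition: FoldPartition,
                lam: float = 0.01) -> float:
    """Mean cross-validated accuracy over folds and balancing repeats."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError("X rows and labels disagree")
    accs = []
    for train, test in partition:
        model = fit_lda(X[train], y[train], lam=lam)
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return float(np.mean(accs))
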