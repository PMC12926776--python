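"""Cross-task decoding: temporal generalization and the spectral variant.

The classifier is trained at each timepoint of one task and tested at
every timepoint of the other, yielding a rectangular train-time x
test-time accuracy matrix per subject.  Training uses all (balanced)
trials of the training task — no trial of the training task is ever
scored, so cross-validation is unnecessary.  Both tasks are subsampled to
a common per-condition trial count (the minimum across the two tasks) so
accuracy is comparable across task pairs.  Directions A->B and B->A are
computed separately and never averaged; asymmetries are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .decoder import fit_lda
from .epochs import EpochSet
from .within import FrequencyFeatureConfig, _zscore_train_test, fft_power_features

__all__ = ["GeneralizationMatrix", "cross_task_matrix", "cross_task_frequency"]


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time accuracies for one direction and subject."""

    train_task: str
    test_task: str
    train_times: np.ndarray
    test_times: np.ndarray
    values: np.ndarray
    label_type: str = "condition"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.train_times.size, self.test_times.size)
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")


def _balanced_subsample(y: np.ndarray, m: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Indices of m trials per class, subsampled without replacement."""
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < m:
            raise ValueError("class smaller than requested balance count")
        keep.append(rng.choice(idx, size=m, replace=False) if idx.size > m
                    else idx)
    return np.sort(np.concatenate(keep))


def _prepare_pair(train: EpochSet, test: EpochSet, label_type: str,
                  seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if train.channels != test.channels:
        raise ValueError(
            "channel sets differ between tasks; run harmonize_channels first")
    y_tr = train.labels(label_type)
    y_te = test.labels(label_type)
    counts = [np.sum(y_tr == c) for c in (0, 1)] + \
             [np.sum(y_te == c) for c in (0, 1)]
    m = int(min(counts))
    if m < 2:
        raise ValueError("need at least two trials per class in both tasks")
    rng = np.random.default_rng(seed)
    i_tr = _balanced_subsample(y_tr, m, rng)
    i_te = _balanced_subsample(y_te, m, rng)
    return i_tr, y_tr[i_tr], i_te, y_te[i_te]


def cross_task_matrix(train: EpochSet, test: EpochSet, lam: float = 0.01,
                      seed: int = 0,
                      label_type: str = "condition") -> GeneralizationMatrix:
    """Temporal generalization from ``train`` task to ``test`` task."""
    i_tr, y_tr, i_te, y_te = _prepare_pair(train, test, label_type, seed)
    Xtr = train.data[i_tr]  # trials x channels x train_times
    Xte = test.data[i_te]
    n_t_train = train.n_times
    values = np.empty((n_t_train, test.n_times))
    for t in range(n_t_train):
        model = fit_lda(Xtr[:, :, t], y_tr, lam=lam)
        # decision values at every test timepoint at once
        d = np.einsum("nct,c->nt", Xte, model.weights) + model.bias
        pred = (d > 0).astype(int)
        values[t] = (pred == y_te[:, None]).mean(axis=0)
    return GeneralizationMatrix(
        train_task=train.task_id, test_task=test.task_id,
        train_times=train.times.copy(), test_times=test.times.copy(),
        values=values, label_type=label_type,
        metadata={"subject": train.subject_id, "lam": lam, "seed": seed,
                  "n_per_condition": int(y_tr.size // 2)})


def cross_task_frequency(train: EpochSet, test: EpochSet,
                         fconfig: FrequencyFeatureConfig | None = None,
                         lam: float = 0.01, seed: int = 0,
                         label_type: str = "condition") -> float:
    """Train on one task's spectral features, test on the other's.

    The z-transformation is fitted on the training task only and applied
    unchanged to the test task.
    """
    fconfig = fconfig or FrequencyFeatureConfig()
    i_tr, y_tr, i_te, y_te = _prepare_pair(train, test, label_type, seed)
    Xtr, _ = fft_power_features(train.select_trials(i_tr), fconfig)
    Xte, _ = fft_power_features(test.select_trials(i_te), fconfig)
    zt, zs = _zscore_train_test(Xtr, Xte)
    model = fit_lda(zt, y_tr, lam=lam)
    return float(np.mean(model.predict(zs) == y_te))
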