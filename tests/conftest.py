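"""Shared fixtures: hand-built epoch sets and small synthetic recipes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conflictdecode.epochs import EpochSet


def build_epochs(data: np.ndarray, sample_rate: float = 100.0,
                 t_start: float = -200.0, conditions=None, hands=None,
                 rts=None, correct=None, subject="sub-01", task="task") -> EpochSet:
    """EpochSet from a raw tensor with simple default annotations."""
    n_trials, _, n_t = data.shape
    times = t_start + np.arange(n_t) * 1000.0 / sample_rate
    if conditions is None:
        conditions = np.where(np.arange(n_trials) % 2 == 0, "conflict",
                              "nonconflict")
    trials = pd.DataFrame({
        "condition": conditions,
        "response_hand": hands if hands is not None else "right",
        "rt_ms": rts if rts is not None else 500.0,
        "correct": correct if correct is not None else 1,
    })
    n_ch = data.shape[1]
    channels = tuple(f"ch{i:02d}" for i in range(n_ch))
    return EpochSet(subject_id=subject, task_id=task, sample_rate=sample_rate,
                    times=times, channels=channels, data=data, trials=trials)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def noise_epochs(rng) -> EpochSet:
    """60 trials x 4 channels of white noise spanning -100..1190 ms."""
    data = rng.normal(0, 10.0, size=(60, 4, 130))
    return build_epochs(data, t_start=-100.0)


def planted_epochs(rng, n_per_class: int = 60, n_ch: int = 6, n_t: int = 120,
                   sample_rate: float = 100.0, t_start: float = -200.0,
                   window=(250.0, 450.0), amplitude: float = 8.0,
                   pattern=None) -> EpochSet:
    """Noise epochs with a boxcar class effect confined to ``window``."""
    n = 2 * n_per_class
    data = rng.normal(0, 10.0, size=(n, n_ch, n_t))
    times = t_start + np.arange(n_t) * 1000.0 / sample_rate
    if pattern is None:
        pattern = np.zeros(n_ch)
        pattern[0] = 1.0
    gate = (times >= window[0]) & (times <= window[1])
    conditions = np.array(["conflict"] * n_per_class + ["nonconflict"] * n_per_class)
    data[:n_per_class] += amplitude * np.asarray(pattern)[:, None] * gate[None, :]
    return build_epochs(data, sample_rate=sample_rate, t_start=t_start,
                        conditions=conditions)
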