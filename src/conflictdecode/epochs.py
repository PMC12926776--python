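"""Epoched EEG container, on-disk round trip, trial tables, EEGLAB import.

An :class:`EpochSet` holds one subject's epochs for one task as a
``trials x channels x timepoints`` tensor in microvolts, together with the
per-trial annotations (condition, response hand, reaction time,
correctness) that every decoding analysis keys on.  Time is in
milliseconds relative to stimulus onset, which is sample ``t = 0``.

On disk each epoch set is one ``.npy`` array store plus a JSON metadata
sidecar; the round trip is bit-exact.  Trial tables are tab-delimited text
with the documented header (subject, task, trial, condition,
response_hand, rt_ms, correct).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "CONDITIONS",
    "save_epochs",
    "load_epochs",
    "read_trial_table",
    "write_trial_table",
    "read_eeglab_epochs",
    "TRIAL_TABLE_COLUMNS",
]

CONDITIONS = ("conflict", "nonconflict")
RESPONSE_HANDS = ("left", "right", "none")
TRIAL_TABLE_COLUMNS = ["subject", "task", "trial", "condition", "response_hand",
                       "rt_ms", "correct"]


@dataclass
class EpochSet:
    """Epoched EEG for one subject and one task.

    Attributes
    ----------
    subject_id, task_id : str
        Identify the recording.
    sample_rate : float
        Sampling rate in Hz.
    times : ndarray, shape (n_times,)
        Sample times in ms relative to stimulus onset; strictly increasing
        with uniform spacing ``1000 / sample_rate``.
    channels : tuple of str
        Channel labels, one per tensor row.
    data : ndarray, shape (n_trials, n_channels, n_times)
        Voltages in microvolts.
    trials : DataFrame
        One row per trial with columns ``condition`` (conflict /
        nonconflict), ``response_hand`` (left / right / none), ``rt_ms``
        (NaN when no response) and ``correct`` (0/1).
    """

    subject_id: str
    task_id: str
    sample_rate: float
    times: np.ndarray
    channels: tuple[str, ...]
    data: np.ndarray
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_trials, n_ch, n_t = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError(f"{len(self.channels)} channel labels for {n_ch} rows")
        if n_t != self.times.size:
            raise ValueError(f"{self.times.size} time labels for {n_t} samples")
        if n_t >= 2:
            dt = np.diff(self.times)
            step = 1000.0 / self.sample_rate
            if np.any(dt <= 0) or not np.allclose(dt, step, rtol=0, atol=1e-6):
                raise ValueError("times must increase uniformly at 1000/sample_rate ms")
        if len(self.trials) != n_trials:
            raise ValueError(f"{len(self.trials)} annotation rows for {n_trials} trials")
        bad = set(self.trials["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        self.trials = self.trials.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def labels(self, label_type: str = "condition") -> np.ndarray:
        """Binary class labels: 1 = conflict (or right hand), 0 otherwise."""
        if label_type == "condition":
            return (self.trials["condition"].to_numpy() == "conflict").astype(int)
        if label_type == "response_hand":
            hands = self.trials["response_hand"].to_numpy()
            if not set(hands) <= {"left", "right"}:
                raise ValueError("response-hand decoding requires only left/right trials")
            return (hands == "right").astype(int)
        raise ValueError(f"unknown label_type {label_type!r}")

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def window_indices(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Sample indices with ``start_ms <= t <= end_ms`` (closed interval)."""
        idx = np.flatnonzero((self.times >= start_ms - 1e-9) & (self.times <= end_ms + 1e-9))
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {end_ms}] ms is outside the epoch")
        return idx

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(self, data=self.data[index],
                       trials=self.trials.iloc[index].reset_index(drop=True))

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), times=self.times.copy(),
                       trials=self.trials.copy())


# ---------------------------------------------------------------------------
# container I/O: <stem>.npy + <stem>.json
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` (data tensor) and ``<stem>.json`` (metadata)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, epochs.data)
    payload = {
        "subject_id": epochs.subject_id,
        "task_id": epochs.task_id,
        "sample_rate": epochs.sample_rate,
        "times": epochs.times.tolist(),
        "channels": list(epochs.channels),
        "trials": {
            "condition": epochs.trials["condition"].tolist(),
            "response_hand": epochs.trials["response_hand"].tolist(),
            "rt_ms": [None if pd.isna(v) else float(v) for v in epochs.trials["rt_ms"]],
            "correct": [int(v) for v in epochs.trials["correct"]],
        },
    }
    meta.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return npy, meta


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    payload = json.loads(stem.with_suffix(".json").read_text())
    tr = payload["trials"]
    trials = pd.DataFrame({
        "condition": tr["condition"],
        "response_hand": tr["response_hand"],
        "rt_ms": [np.nan if v is None else v for v in tr["rt_ms"]],
        "correct": tr["correct"],
    })
    return EpochSet(subject_id=payload["subject_id"], task_id=payload["task_id"],
                    sample_rate=payload["sample_rate"],
                    times=np.array(payload["times"], dtype=float),
                    channels=tuple(payload["channels"]), data=data, trials=trials)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the tab-delimited trial table with the documented header."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[TRIAL_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return table


def trial_table_from_epochs(epochs: EpochSet) -> pd.DataFrame:
    """Per-trial behavioral table for one epoch set."""
    t = epochs.trials
    return pd.DataFrame({
        "subject": epochs.subject_id,
        "task": epochs.task_id,
        "trial": np.arange(len(t)),
        "condition": t["condition"].to_numpy(),
        "response_hand": t["response_hand"].to_numpy(),
        "rt_ms": t["rt_ms"].to_numpy(),
        "correct": t["correct"].to_numpy(),
    })


# ---------------------------------------------------------------------------
# EEGLAB .set import
# ---------------------------------------------------------------------------

def read_eeglab_epochs(path: str | Path, subject_id: str = "unknown",
                       task_id: str = "unknown",
                       condition_map: dict[str, str] | None = None) -> EpochSet:
    """Import an EEGLAB ``.set`` epoch file into an :class:`EpochSet`.

    Parsing is delegated to :func:`mne.io.read_epochs_eeglab`; the epoch
    event type of each trial is mapped onto the ``condition`` annotation
    via ``condition_map`` (default: identity for names already in
    ``{"conflict", "nonconflict"}``).  Response hand, RT and correctness
    are not stored in plain ``.set`` epoch structures and are filled with
    neutral defaults — merge a trial table afterwards when available.
    Voltages are returned in microvolts.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_epochs_eeglab(str(path), verbose="error")
    inv = {v: k for k, v in raw.event_id.items()}
    names = [inv[code] for code in raw.events[:, 2]]
    condition_map = condition_map or {}
    conditions = []
    for name in names:
        cond = condition_map.get(name, name)
        if cond not in CONDITIONS:
            raise ValueError(
                f"event type {name!r} not mapped to conflict/nonconflict; "
                "pass condition_map")
        conditions.append(cond)
    data = raw.get_data(copy=True) * 1e6  # MNE stores volts
    trials = pd.DataFrame({
        "condition": conditions,
        "response_hand": "none",
        "rt_ms": np.nan,
        "correct": 1,
    })
    return EpochSet(subject_id=subject_id, task_id=task_id,
                    sample_rate=float(raw.info["sfreq"]),
                    times=raw.times * 1000.0,
                    channels=tuple(raw.ch_names), data=data, trials=trials)
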