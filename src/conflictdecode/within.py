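"""Within-task decoding: time-resolved, frequency-domain, and searchlights.

Time-resolved decoding trains and tests the classifier independently at
every sample, using all channels' amplitudes at that sample as features;
the cross-validation partition is drawn once per subject and reused
across timepoints, so cells of the resulting map differ only in their
features, never in their trial split.  Frequency-domain decoding replaces
time with spectral power: a DFT of the 0-1000 ms window yields per-trial
channel x frequency power features (1-50 Hz by default), z-scored
fold-wise, giving a single accuracy per subject.  The two searchlights
decode single features — one (channel, time) or (channel, frequency) cell
at a time — to localize information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .decoder import FoldPartition, balanced_partition, cv_accuracy, fit_lda
from .epochs import EpochSet

__all__ = ["DecodingMap", "FrequencyFeatureConfig", "decode_timecourse",
           "searchlight_time", "fft_power_features", "decode_frequency",
           "searchlight_frequency"]

REPORT_TIMES_MS = (252.0, 500.0, 752.0, 1000.0, 1500.0)
REPORT_FREQS_HZ = (3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass
class DecodingMap:
    """Accuracy values on a named grid (one subject layer).

    ``axes`` maps axis names to coordinate vectors, in the order of the
    ``values`` dimensions; e.g. ``{"time": times}`` for a timecourse or
    ``{"channel": labels, "frequency": freqs}`` for a spectral
    searchlight.  ``chance`` is 0.5 for balanced two-class decoding.
    """

    axes: dict[str, np.ndarray]
    values: np.ndarray
    chance: float = 0.5
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = tuple(len(np.atleast_1d(v)) for v in self.axes.values())
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} does not match "
                             f"axes {shape}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class FrequencyFeatureConfig:
    """Spectral feature extraction settings.

    ``window`` is the DFT segment in ms (closed interval on the sample
    grid); ``freq_range`` selects the retained bins.  The bin spacing is
    the DFT resolution ``sample_rate / n_window_samples`` — close to 1 Hz
    for a one-second window.  ``z_transform`` is "fold-wise" (train-fold
    mean/SD applied to the test fold; no leakage) or "global".
    """

    window: tuple[float, float] = (0.0, 1000.0)
    freq_range: tuple[float, float] = (1.0, 50.0)
    taper: str = "none"
    z_transform: str = "fold-wise"

    def __post_init__(self) -> None:
        if self.taper not in ("none", "hann"):
            raise ValueError("taper must be 'none' or 'hann'")
        if self.z_transform not in ("fold-wise", "global"):
            raise ValueError("z_transform must be 'fold-wise' or 'global'")
        if self.freq_range[0] <= 0:
            raise ValueError("freq_range must start above 0 Hz")


def _partition(epochs: EpochSet, k: int, seed: int, n_repeats: int,
               label_type: str) -> tuple[np.ndarray, FoldPartition]:
    y = epochs.labels(label_type)
    return y, balanced_partition(y, k=k, n_repeats=n_repeats, seed=seed)


def decode_timecourse(epochs: EpochSet, lam: float = 0.01, k: int = 10,
                      seed: int = 0, n_repeats: int = 1,
                      label_type: str = "condition") -> DecodingMap:
    """Balanced k-fold accuracy at every sample (features = all channels)."""
    y, part = _partition(epochs, k, seed, n_repeats, label_type)
    values = np.array([cv_accuracy(epochs.data[:, :, t], y, part, lam=lam)
                       for t in range(epochs.n_times)])
    return DecodingMap(axes={"time": epochs.times.copy()}, values=values,
                       metadata={"task": epochs.task_id, "subject": epochs.subject_id,
                                 "label_type": label_type, "lam": lam, "k": k,
                                 "seed": seed})


def _single_feature_cv(features: np.ndarray, y: np.ndarray,
                       part: FoldPartition, lam: float) -> np.ndarray:
    """Vectorized balanced-CV accuracy for many single-feature decoders.

    ``features`` has shape (n_trials, n_cells); each column is an
    independent one-dimensional LDA problem.  For p = 1 the shrunk
    covariance is the pooled variance itself (shrinkage is a no-op up to
    scale), so the decision rule reduces to the midpoint threshold
    between class means, with the sign of (mu1 - mu0) as orientation and
    ties going to class 0.  Accuracies are averaged over folds exactly
    like :func:`~conflictdecode.decoder.cv_accuracy`.
    """
    acc = np.zeros(features.shape[1])
    n_folds = 0
    for train, test in part:
        xt, yt = features[train], y[train]
        mu0 = xt[yt == 0].mean(axis=0)
        mu1 = xt[yt == 1].mean(axis=0)
        mid = (mu0 + mu1) / 2.0
        sign = np.sign(mu1 - mu0)
        d = (features[test] - mid) * sign  # > 0 -> class 1, ties -> class 0
        pred = (d > 0).astype(int)
        acc += (pred == y[test][:, None]).mean(axis=0)
        n_folds += 1
    return acc / n_folds


def searchlight_time(epochs: EpochSet, lam: float = 0.01, k: int = 10,
                     seed: int = 0, n_repeats: int = 1,
                     label_type: str = "condition",
                     report_times: tuple[float, ...] = REPORT_TIMES_MS,
                     ) -> tuple[DecodingMap, dict[float, np.ndarray]]:
    """Single-feature decoding per (channel, timepoint).

    Returns the full channel x time map and topographies at the requested
    report times (snapped to the nearest sample when off the grid; the
    snapped time is the key of the returned dict).
    """
    y, part = _partition(epochs, k, seed, n_repeats, label_type)
    n_tr, n_ch, n_t = epochs.data.shape
    feats = epochs.data.reshape(n_tr, n_ch * n_t)
    acc = _single_feature_cv(feats, y, part, lam).reshape(n_ch, n_t)
    dmap = DecodingMap(axes={"channel": np.array(epochs.channels),
                             "time": epochs.times.copy()}, values=acc,
                       metadata={"task": epochs.task_id,
                                 "subject": epochs.subject_id,
                                 "label_type": label_type, "lam": lam, "k": k,
                                 "seed": seed})
    topos = {}
    for t in report_times:
        if not (epochs.times[0] <= t <= epochs.times[-1]):
            continue
        snapped = float(epochs.times[epochs.time_index(t)])
        topos[snapped] = acc[:, epochs.time_index(t)].copy()
    return dmap, topos


def fft_power_features(epochs: EpochSet,
                       fconfig: FrequencyFeatureConfig | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spectral power features (channel-major ordering).

    Returns ``(features, bin_freqs)`` where features has shape
    ``(n_trials, n_channels * n_bins)``; the columns run over channels
    first, each channel contributing its retained frequency bins in
    ascending order.  Power is the squared DFT magnitude of the windowed
    segment.
    """
    fconfig = fconfig or FrequencyFeatureConfig()
    lo, hi = fconfig.window
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ValueError(f"FFT window {fconfig.window} ms lies outside the "
                         f"epoch span [{epochs.times[0]}, {epochs.times[-1]}]")
    idx = epochs.window_indices(lo, hi)
    seg = epochs.data[:, :, idx]
    if fconfig.taper == "hann":
        seg = seg * np.hanning(idx.size)[None, None, :]
    if fconfig.freq_range[1] > epochs.sample_rate / 2:
        raise ValueError("freq_range exceeds the Nyquist frequency")
    spect = np.fft.rfft(seg, axis=2)
    power = np.abs(spect) ** 2
    freqs = np.fft.rfftfreq(idx.size, d=1.0 / epochs.sample_rate)
    keep = (freqs >= fconfig.freq_range[0] - 1e-9) & \
           (freqs <= fconfig.freq_range[1] + 1e-9)
    power = power[:, :, keep]
    n_tr = power.shape[0]
    return power.reshape(n_tr, -1), freqs[keep]


def _zscore_train_test(train_X: np.ndarray, test_X: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    zero = sd == 0
    sd = np.where(zero, 1.0, sd)
    zt = (train_X - mu) / sd
    zs = (test_X - mu) / sd
    if zero.any():  # zero-variance features carry no information: z := 0
        zt[:, zero] = 0.0
        zs[:, zero] = 0.0
    return zt, zs


def decode_frequency(epochs: EpochSet,
                     fconfig: FrequencyFeatureConfig | None = None,
                     lam: float = 0.01, k: int = 10, seed: int = 0,
                     n_repeats: int = 1, label_type: str = "condition") -> float:
    """Single balanced k-fold accuracy on spectral power features."""
    fconfig = fconfig or FrequencyFeatureConfig()
    X, _ = fft_power_features(epochs, fconfig)
    y, part = _partition(epochs, k, seed, n_repeats, label_type)
    if fconfig.z_transform == "global":
        X, _ = _zscore_train_test(X, X[:0])
        return cv_accuracy(X, y, part, lam=lam)
    accs = []
    for train, test in part:
        zt, zs = _zscore_train_test(X[train], X[test])
        model = fit_lda(zt, y[train], lam=lam)
        accs.append(float(np.mean(model.predict(zs) == y[test])))
    return float(np.mean(accs))


def searchlight_frequency(epochs: EpochSet,
                          fconfig: FrequencyFeatureConfig | None = None,
                          lam: float = 0.01, k: int = 10, seed: int = 0,
                          n_repeats: int = 1, label_type: str = "condition",
                          report_freqs: tuple[float, ...] = REPORT_FREQS_HZ,
                          ) -> tuple[DecodingMap, np.ndarray, dict[float, np.ndarray]]:
    """Single-feature decoding per (channel, frequency bin).

    Returns the channel x frequency map, the channel-averaged
    accuracy-by-frequency profile, and topographies at the report
    frequencies (snapped to the nearest bin).
    """
    fconfig = fconfig or FrequencyFeatureConfig()
    X, freqs = fft_power_features(epochs, fconfig)
    y, part = _partition(epochs, k, seed, n_repeats, label_type)
    n_ch = epochs.n_channels
    acc = _single_feature_cv(X, y, part, lam).reshape(n_ch, freqs.size)
    dmap = DecodingMap(axes={"channel": np.array(epochs.channels),
                             "frequency": freqs.copy()}, values=acc,
                       metadata={"task": epochs.task_id,
                                 "subject": epochs.subject_id,
                                 "label_type": label_type, "lam": lam, "k": k,
                                 "seed": seed})
    profile = acc.mean(axis=0)
    topos = {}
    for f in report_freqs:
        if freqs.size == 0 or not (freqs[0] - 0.5 <= f <= freqs[-1] + 0.5):
            continue
        j = int(np.argmin(np.abs(freqs - f)))
        topos[float(freqs[j])] = acc[:, j].copy()
    return dmap, profile, topos
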