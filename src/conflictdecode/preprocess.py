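"""Preprocessing chain: FIR filtering, decimation, baseline removal,
channel harmonization and behavioral trial screening.

The canonical order is ``fir_filter -> downsample -> crop -> baseline_correct``
(:func:`preprocess` applies it); all operations are pure and return new
:class:`~conflictdecode.epochs.EpochSet` objects.

Filtering uses a Hamming-windowed sinc FIR kernel applied zero-phase: the
kernel is linear-phase (symmetric, odd length) and is convolved in "same"
mode, which realizes a single forward pass with exact group-delay
compensation.  The transition bandwidth follows the documented rule
``tb = min(max(0.25 * hp, 2 Hz), 0.25 * lp)`` and the kernel length is
``ceil(3.3 * fs / tb)`` rounded up to odd — the conventional Hamming-window
design rule.  The transition is additionally capped at twice the high-pass
cutoff so the lower stopband edge stays at or above DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

from .epochs import EpochSet

__all__ = [
    "PreprocessConfig",
    "ScreeningRules",
    "design_fir_kernel",
    "fir_filter",
    "downsample",
    "baseline_correct",
    "harmonize_channels",
    "screen_trials",
    "preprocess",
]

DEFAULT_RT_MAX = {"change_detection": 1800.0, "simon": 1500.0,
                  "stroop_reading": 4000.0, "stroop_naming": 4000.0}


@dataclass(frozen=True)
class ScreeningRules:
    """Behavioral trial screening.

    ``rt_max_ms`` maps task ids to the slowest admissible response
    (defaults: 1800 ms change detection, 1500 ms Simon, 4000 ms Stroop);
    ``premature_ms`` is the fastest plausible response — anything quicker
    counts as premature.  ``require_response`` drops no-response trials;
    ``correct_only`` additionally drops errors (off by default).
    """

    rt_max_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RT_MAX))
    default_rt_max_ms: float = 4000.0
    premature_ms: float = 100.0
    require_response: bool = True
    correct_only: bool = False

    def __post_init__(self) -> None:
        if self.premature_ms < 0:
            raise ValueError("premature_ms must be >= 0")
        for task, mx in self.rt_max_ms.items():
            if mx <= self.premature_ms:
                raise ValueError(f"rt_max for {task!r} must exceed premature_ms")

    def rt_max(self, task_id: str) -> float:
        return self.rt_max_ms.get(task_id, self.default_rt_max_ms)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter cutoffs, target rate, epoch and baseline windows, screening.

    The baseline window default is the post-stimulus interval [0, 200] ms;
    it is configurable (``baseline_window=(-200, 0)`` gives the classical
    pre-stimulus convention).
    """

    hp_cutoff: float = 0.5
    lp_cutoff: float = 100.0
    target_rate: float = 250.0
    baseline_window: tuple[float, float] = (0.0, 200.0)
    epoch_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    screening: ScreeningRules = field(default_factory=ScreeningRules)

    def __post_init__(self) -> None:
        if not (0 < self.hp_cutoff < self.lp_cutoff < self.target_rate / 2):
            raise ValueError(
                "cutoffs must satisfy 0 < hp_cutoff < lp_cutoff < target_rate/2 "
                f"(got hp={self.hp_cutoff}, lp={self.lp_cutoff}, "
                f"target={self.target_rate})")


def _transition_bandwidth(hp: float, lp: float) -> float:
    # 25% of the cutoff, at least 2 Hz, never wider than a quarter of the
    # low-pass edge — and capped at twice the high-pass cutoff so the
    # lower transition band never crosses DC (otherwise a low cutoff such
    # as 0.5 Hz would leave drift essentially unattenuated)
    return min(max(0.25 * hp, 2.0), 0.25 * lp, 2.0 * hp)


def design_fir_kernel(sample_rate: float, hp_cutoff: float, lp_cutoff: float) -> np.ndarray:
    """Hamming-windowed sinc band-pass kernel (odd length, linear phase)."""
    if lp_cutoff >= sample_rate / 2:
        raise ValueError(
            f"lp_cutoff {lp_cutoff} Hz violates the Nyquist limit "
            f"{sample_rate / 2} Hz at sample rate {sample_rate} Hz")
    if hp_cutoff <= 0:
        raise ValueError(f"hp_cutoff must be positive, got {hp_cutoff}")
    tb = _transition_bandwidth(hp_cutoff, lp_cutoff)
    numtaps = int(np.ceil(3.3 * sample_rate / tb))
    numtaps += 1 - numtaps % 2  # force odd for exact linear-phase centering
    return firwin(numtaps, [hp_cutoff, lp_cutoff], pass_zero=False,
                  window="hamming", fs=sample_rate)


def fir_filter(epochs: EpochSet, config: PreprocessConfig) -> EpochSet:
    """Zero-phase band-pass filter every trial and channel."""
    if epochs.sample_rate <= 2 * config.lp_cutoff:
        raise ValueError(
            f"sample rate {epochs.sample_rate} Hz too low for lp_cutoff "
            f"{config.lp_cutoff} Hz")
    kernel = design_fir_kernel(epochs.sample_rate, config.hp_cutoff, config.lp_cutoff)
    # symmetric odd-length kernel + "same" mode == forward pass with the
    # group delay compensated; edges see implicit zero padding
    filtered = fftconvolve(epochs.data, kernel[None, None, :], mode="same", axes=2)
    return replace(epochs, data=filtered, trials=epochs.trials.copy())


def downsample(epochs: EpochSet, target_rate: float) -> EpochSet:
    """Decimate to ``target_rate`` keeping t = 0 on the sample grid.

    The decimation factor must be an integer; anti-alias filtering is the
    chain's preceding low-pass (``fir_filter``) — no extra filter is
    applied here.
    """
    factor = epochs.sample_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sample rate {epochs.sample_rate} Hz is not an integer multiple "
            f"of target rate {target_rate} Hz")
    factor = int(round(factor))
    if factor == 1:
        return epochs.copy()
    i0 = epochs.time_index(0.0)
    offset = i0 % factor
    sl = slice(offset, None, factor)
    return replace(epochs, sample_rate=float(target_rate),
                   times=epochs.times[sl].copy(), data=epochs.data[:, :, sl],
                   trials=epochs.trials.copy())


def crop(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Restrict the epoch to ``window`` (closed interval on the sample grid)."""
    idx = epochs.window_indices(*window)
    return replace(epochs, times=epochs.times[idx].copy(),
                   data=epochs.data[:, :, idx], trials=epochs.trials.copy())


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (0.0, 200.0)) -> EpochSet:
    """Subtract each trial's and channel's mean over the baseline window."""
    idx = epochs.window_indices(*window)
    base = epochs.data[:, :, idx].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, trials=epochs.trials.copy())


def harmonize_channels(epoch_sets: list[EpochSet]) -> list[EpochSet]:
    """Restrict every set to the shared channels, in canonical order."""
    if not epoch_sets:
        raise ValueError("need at least one epoch set")
    common = set(epoch_sets[0].channels)
    for es in epoch_sets[1:]:
        common &= set(es.channels)
    if not common:
        raise ValueError("channel intersection across epoch sets is empty")
    order = sorted(common)
    out = []
    for es in epoch_sets:
        idx = [es.channels.index(c) for c in order]
        out.append(replace(es, channels=tuple(order), data=es.data[:, idx, :],
                           trials=es.trials.copy()))
    return out


def screen_trials(epochs: EpochSet,
                  rules: ScreeningRules | None = None) -> tuple[EpochSet, dict[str, int]]:
    """Drop no-response, premature, too-slow and (optionally) error trials.

    Returns the screened epoch set (trial order preserved) and a report of
    counts dropped per reason.  Reasons are assessed in order — a trial is
    charged to the first rule it violates.
    """
    rules = rules or ScreeningRules()
    rt = epochs.trials["rt_ms"].to_numpy(dtype=float)
    correct = epochs.trials["correct"].to_numpy()
    rt_max = rules.rt_max(epochs.task_id)

    no_response = ~np.isfinite(rt)
    premature = np.isfinite(rt) & (rt < rules.premature_ms)
    too_slow = np.isfinite(rt) & (rt > rt_max)
    report = {
        "n_input": epochs.n_trials,
        "no_response": int(no_response.sum()) if rules.require_response else 0,
        "premature": int(premature.sum()),
        "too_slow": int(too_slow.sum()),
    }
    drop = premature | too_slow
    if rules.require_response:
        drop |= no_response
    if rules.correct_only:
        incorrect = ~drop & (correct == 0)
        report["incorrect"] = int(incorrect.sum())
        drop |= incorrect
    else:
        report["incorrect"] = 0
    keep = np.flatnonzero(~drop)
    report["n_retained"] = int(keep.size)
    report["empty_result"] = bool(keep.size == 0)
    return epochs.select_trials(keep), report


def preprocess(epochs: EpochSet,
               config: PreprocessConfig | None = None) -> tuple[EpochSet, dict[str, int]]:
    """Canonical chain: filter -> downsample -> crop -> baseline -> screen."""
    config = config or PreprocessConfig()
    out = fir_filter(epochs, config)
    out = downsample(out, config.target_rate)
    window = config.epoch_windows.get(epochs.task_id)
    if window is not None:
        out = crop(out, window)
    out = baseline_correct(out, config.baseline_window)
    return screen_trials(out, config.screening)
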