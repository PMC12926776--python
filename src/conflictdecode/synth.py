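"""Synthetic multi-subject, multi-task EEG with planted conflict effects.

The generator emulates a multi-session conflict-task battery: several
"tasks" with task-specific epoch windows and unequal conflict /
non-conflict trial counts, where the conflict condition carries

* a transient **evoked** spatial pattern (a time-bump projected onto the
  task's effect topography), and
* an **induced** theta-band (3-7 Hz by default) oscillation with uniform
  random phase per trial, gated to the 0-1000 ms analysis window — phase
  randomness makes it invisible to trial-averaged potentials but visible
  to spectral power features.

Each task's effect topography is a controllable mixture of a common
fronto-central template and a task-unique orthogonal pattern,

    pattern = alpha * shared + sqrt(1 - alpha^2) * unique,

so ``overlap_alpha`` dials the ground truth from fully shared (alpha = 1,
cross-task decodable) to fully task-specific (alpha = 0, orthogonal).
Background activity is 1/f-spectrum noise, spatially mixed across
channels; behavior is lognormal RTs (slower under conflict) and Bernoulli
correctness (less accurate under conflict).  An optional lateralized
motor pattern time-locked to the response separates left- from right-hand
trials with a topography shared across tasks — the response-hand control.

Randomness: one root ``numpy`` SeedSequence per dataset, spawned per
subject x task in declaration order; within a task the draw order is
fixed (response hands -> noise -> effect phases -> RT -> correctness), so
identical ``(config, seed)`` pairs yield bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet, trial_table_from_epochs
from .montage import ElectrodeMontage, default_montage

__all__ = ["TaskRecipe", "SynthConfig", "SynthDataset", "generate_dataset",
           "generate_null_dataset", "demo_config"]

THETA_GATE_MS = (0.0, 1000.0)


@dataclass(frozen=True)
class TaskRecipe:
    """Generative recipe for one task.

    Amplitudes are in microvolts, times in ms.  ``evoked_shape`` is
    ``"gaussian"`` (bump ``exp(-(t - latency)^2 / (2 width^2))``) or
    ``"box"`` (constant inside ``latency +- width``, zero outside — useful
    when an effect must be strictly confined to a window).  ``rt_median_ms``
    and ``rt_sigma`` parametrize the lognormal RT per condition;
    ``accuracy`` is the per-condition probability of a correct response.
    """

    task_id: str
    epoch_window: tuple[float, float] = (-500.0, 1500.0)
    n_conflict: int = 76
    n_nonconflict: int = 163
    evoked_amplitude: float = 6.0
    evoked_latency: float = 400.0
    evoked_width: float = 80.0
    evoked_shape: str = "gaussian"
    theta_amplitude: float = 10.0
    theta_band: tuple[float, float] = (3.0, 7.0)
    overlap_alpha: float = 1.0
    motor_amplitude: float = 0.0
    motor_width: float = 100.0
    rt_median_ms: dict[str, float] = field(
        default_factory=lambda: {"conflict": 580.0, "nonconflict": 500.0})
    rt_sigma: dict[str, float] = field(
        default_factory=lambda: {"conflict": 0.25, "nonconflict": 0.25})
    accuracy: dict[str, float] = field(
        default_factory=lambda: {"conflict": 0.85, "nonconflict": 0.95})

    def __post_init__(self) -> None:
        if self.n_conflict <= 0 or self.n_nonconflict <= 0:
            raise ValueError(
                f"task {self.task_id!r}: trial counts must be positive")
        if not 0.0 <= self.overlap_alpha <= 1.0:
            raise ValueError("overlap_alpha must lie in [0, 1]")
        if self.evoked_shape not in ("gaussian", "box"):
            raise ValueError("evoked_shape must be 'gaussian' or 'box'")
        for cond in ("conflict", "nonconflict"):
            if not 0.0 <= self.accuracy[cond] <= 1.0:
                raise ValueError("accuracy rates must lie in [0, 1]")
        lo, hi = self.epoch_window
        if hi <= lo:
            raise ValueError("epoch_window must be increasing")
        if self.theta_amplitude > 0 and (lo > THETA_GATE_MS[0] or hi < THETA_GATE_MS[1]):
            raise ValueError(
                f"task {self.task_id!r}: epoch window {self.epoch_window} must "
                f"cover the {THETA_GATE_MS} ms analysis window when theta "
                "effects are enabled")


@dataclass(frozen=True)
class SynthConfig:
    """Full generative recipe for one dataset."""

    n_subjects: int = 20
    tasks: tuple[TaskRecipe, ...] = ()
    montage: ElectrodeMontage = field(default_factory=default_montage)
    sample_rate: float = 250.0
    noise_alpha: float = 1.0
    noise_sd: float = 10.0
    spatial_mixing: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        ids = [t.task_id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ValueError("task ids must be unique")
        if not 0.0 <= self.spatial_mixing <= 1.0:
            raise ValueError("spatial_mixing must lie in [0, 1]")


@dataclass
class SynthDataset:
    """Generated epochs keyed by ``(subject_id, task_id)`` plus behavior."""

    config: SynthConfig
    epochs: dict[tuple[str, str], EpochSet]
    trial_table: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.epochs})

    @property
    def tasks(self) -> list[str]:
        return [t.task_id for t in self.config.tasks]

    def subject_epochs(self, task_id: str) -> list[EpochSet]:
        return [self.epochs[(s, task_id)] for s in self.subjects]


# ---------------------------------------------------------------------------
# pattern construction
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def shared_template(montage: ElectrodeMontage) -> np.ndarray:
    """Unit-norm fronto-central topography (the common conflict template)."""
    pos = montage.positions
    center = np.array([0.0, 0.35])  # approximately FCz in the head plane
    w = np.exp(-np.sum((pos - center) ** 2, axis=1) / (2 * 0.35 ** 2))
    return _unit(w)


def motor_template(montage: ElectrodeMontage) -> np.ndarray:
    """Unit-norm left-right antisymmetric central topography (response hand)."""
    pos = montage.positions
    central = np.exp(-(pos[:, 1] ** 2) / (2 * 0.4 ** 2))
    return _unit(pos[:, 0] * central)


def task_effect_pattern(recipe: TaskRecipe, montage: ElectrodeMontage) -> np.ndarray:
    """``alpha * shared + sqrt(1 - alpha^2) * unique`` (unit norm).

    The unique component is a deterministic function of the task id
    (hashed into an RNG seed) orthogonalized against the shared template,
    so tasks with ``overlap_alpha = 0`` have mutually independent — and,
    relative to the shared template, exactly orthogonal — topographies.
    """
    shared = shared_template(montage)
    a = recipe.overlap_alpha
    if a >= 1.0:
        return shared
    key = np.frombuffer(recipe.task_id.encode(), dtype=np.uint8)
    rng = np.random.default_rng(np.concatenate([[987654321], key]))
    u = rng.normal(size=montage.n_channels)
    u -= (u @ shared) * shared
    u = _unit(u)
    return a * shared + np.sqrt(1.0 - a * a) * u


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def one_over_f_noise(rng: np.random.Generator, n_trials: int, n_channels: int,
                     n_times: int, sample_rate: float, alpha: float,
                     sd: float) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to ``f^-alpha``.

    Spectral amplitudes scale as ``f^(-alpha/2)`` with random complex
    Gaussian coefficients; the DC bin is zeroed and the result is scaled
    so each channel's standard deviation equals ``sd`` in expectation.
    """
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sample_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    coef = rng.normal(size=(n_trials, n_channels, freqs.size)) \
        + 1j * rng.normal(size=(n_trials, n_channels, freqs.size))
    coef *= amp
    x = np.fft.irfft(coef, n=n_times, axis=2)
    # expected per-sample variance: each interior rfft bin appears with its
    # conjugate (var 4 amp^2 / N^2); an even-N Nyquist bin enters once and
    # only through its real part (var amp^2 / N^2)
    if n_times % 2 == 0:
        expected_var = (4.0 * np.sum(amp[1:-1] ** 2) + amp[-1] ** 2) / n_times ** 2
    else:
        expected_var = 4.0 * np.sum(amp[1:] ** 2) / n_times ** 2
    return x * (sd / np.sqrt(expected_var))


def mixing_matrix(rng: np.random.Generator, n_channels: int,
                  strength: float) -> np.ndarray:
    """Row-normalized blend of the identity with a random rotation."""
    gauss = rng.normal(size=(n_channels, n_channels))
    q, r = np.linalg.qr(gauss)
    q *= np.sign(np.diag(r))  # unique orthogonal factor
    m = (1.0 - strength) * np.eye(n_channels) + strength * q
    return m / np.linalg.norm(m, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _evoked_waveform(recipe: TaskRecipe, times: np.ndarray) -> np.ndarray:
    if recipe.evoked_shape == "box":
        lo = recipe.evoked_latency - recipe.evoked_width
        hi = recipe.evoked_latency + recipe.evoked_width
        return ((times >= lo) & (times <= hi)).astype(float)
    return np.exp(-((times - recipe.evoked_latency) ** 2)
                  / (2.0 * recipe.evoked_width ** 2))


def _generate_task(rng: np.random.Generator, config: SynthConfig,
                   recipe: TaskRecipe, subject_id: str,
                   mix: np.ndarray) -> EpochSet:
    fs = config.sample_rate
    lo, hi = recipe.epoch_window
    n_t = int(round((hi - lo) * fs / 1000.0)) + 1
    times = lo + np.arange(n_t) * 1000.0 / fs
    n_trials = recipe.n_conflict + recipe.n_nonconflict
    conflict = np.zeros(n_trials, dtype=bool)
    conflict[: recipe.n_conflict] = True

    # draw order (documented): hands -> noise -> effect phases -> RT -> correct
    hands = np.where(rng.random(n_trials) < 0.5, "left", "right")
    data = one_over_f_noise(rng, n_trials, config.montage.n_channels, n_t,
                            fs, config.noise_alpha, config.noise_sd)
    data = np.einsum("cd,ndt->nct", mix, data)

    pattern = task_effect_pattern(recipe, config.montage)
    if recipe.evoked_amplitude != 0.0:
        bump = recipe.evoked_amplitude * _evoked_waveform(recipe, times)
        data[conflict] += pattern[:, None] * bump[None, :]
    if recipe.theta_amplitude != 0.0:
        gate = (times >= THETA_GATE_MS[0]) & (times <= THETA_GATE_MS[1])
        f = rng.uniform(*recipe.theta_band, size=n_trials)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
        osc = np.sin(2.0 * np.pi * f[:, None] * times[None, :] / 1000.0
                     + phase[:, None]) * gate[None, :]
        data[conflict] += recipe.theta_amplitude \
            * pattern[None, :, None] * osc[conflict][:, None, :]

    cond = np.where(conflict, "conflict", "nonconflict")
    rt = np.empty(n_trials)
    for c in ("conflict", "nonconflict"):
        m = cond == c
        rt[m] = rng.lognormal(np.log(recipe.rt_median_ms[c]),
                              recipe.rt_sigma[c], size=int(m.sum()))
    if recipe.motor_amplitude != 0.0:
        mt = motor_template(config.montage)
        sign = np.where(hands == "right", 1.0, -1.0)
        bump = np.exp(-((times[None, :] - rt[:, None]) ** 2)
                      / (2.0 * recipe.motor_width ** 2))
        data += recipe.motor_amplitude * sign[:, None, None] \
            * mt[None, :, None] * bump[:, None, :]
    correct = np.empty(n_trials, dtype=int)
    for c in ("conflict", "nonconflict"):
        m = cond == c
        correct[m] = (rng.random(int(m.sum())) < recipe.accuracy[c]).astype(int)

    trials = pd.DataFrame({"condition": cond, "response_hand": hands,
                           "rt_ms": rt, "correct": correct})
    return EpochSet(subject_id=subject_id, task_id=recipe.task_id,
                    sample_rate=fs, times=times,
                    channels=config.montage.labels, data=data, trials=trials)


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate all subject x task epoch sets plus the behavioral table."""
    if not config.tasks:
        raise ValueError("config.tasks is empty")
    root = np.random.SeedSequence(config.seed)
    mix_rng = np.random.default_rng(root.spawn(1)[0])
    mix = mixing_matrix(mix_rng, config.montage.n_channels, config.spatial_mixing)
    epochs: dict[tuple[str, str], EpochSet] = {}
    tables = []
    child_seqs = root.spawn(config.n_subjects * len(config.tasks))
    i = 0
    for s in range(config.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        for recipe in config.tasks:
            rng = np.random.default_rng(child_seqs[i])
            i += 1
            es = _generate_task(rng, config, recipe, subject_id, mix)
            epochs[(subject_id, recipe.task_id)] = es
            tables.append(trial_table_from_epochs(es))
    return SynthDataset(config=config, epochs=epochs,
                        trial_table=pd.concat(tables, ignore_index=True))


def generate_null_dataset(config: SynthConfig, n_trials: int,
                          task_id: str = "null",
                          epoch_window: tuple[float, float] = (-200.0, 1200.0),
                          subject_id: str = "sub-01") -> EpochSet:
    """Label-null epochs: identical generative process for both conditions.

    Trials are pure background noise; conflict / non-conflict labels are
    assigned at random, independently of the data (half and half), so any
    downstream decoding result is a false positive by construction.
    """
    if n_trials <= 0:
        raise ValueError(f"n_trials must be positive, got {n_trials}")
    recipe = TaskRecipe(task_id=task_id, epoch_window=epoch_window,
                        n_conflict=max(n_trials // 2, 1),
                        n_nonconflict=max(n_trials - n_trials // 2, 1),
                        evoked_amplitude=0.0, theta_amplitude=0.0)
    cfg = replace(config, n_subjects=1, tasks=(recipe,))
    root = np.random.SeedSequence(cfg.seed)
    mix_rng = np.random.default_rng(root.spawn(1)[0])
    mix = mixing_matrix(mix_rng, cfg.montage.n_channels, cfg.spatial_mixing)
    rng = np.random.default_rng(root.spawn(2)[1])
    es = _generate_task(rng, cfg, recipe, subject_id, mix)
    # shuffle the label column only: labels independent of the data
    perm = rng.permutation(es.n_trials)
    trials = es.trials.copy()
    trials["condition"] = trials["condition"].to_numpy()[perm]
    return replace(es, trials=trials)


def demo_config(n_subjects: int = 20, seed: int = 0,
                sample_rate: float = 100.0,
                alpha_shared: float = 1.0,
                alpha_specific: float = 0.0,
                motor_amplitude: float = 0.0) -> SynthConfig:
    """Three-task demo: tasks A and B share the conflict topography
    (``overlap_alpha = alpha_shared``), task C is orthogonal
    (``overlap_alpha = alpha_specific``).

    Trial counts follow the study-battery scale (unequal counts in task A,
    ~50 per condition in task B, ~225 in task C).  The epoch window
    (-200..1200 ms) covers the 0-1000 ms spectral window plus the evoked
    latencies; the demo sample rate trades temporal resolution for
    runtime and is configurable.
    """
    common = dict(epoch_window=(-200.0, 1200.0),
                  motor_amplitude=motor_amplitude)
    tasks = (
        TaskRecipe(task_id="taskA", n_conflict=76, n_nonconflict=163,
                   evoked_latency=400.0, overlap_alpha=alpha_shared, **common),
        TaskRecipe(task_id="taskB", n_conflict=52, n_nonconflict=52,
                   evoked_latency=500.0, overlap_alpha=alpha_shared, **common),
        TaskRecipe(task_id="taskC", n_conflict=226, n_nonconflict=229,
                   evoked_latency=400.0, overlap_alpha=alpha_specific, **common),
    )
    return SynthConfig(n_subjects=n_subjects, tasks=tasks,
                       sample_rate=sample_rate, seed=seed)
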