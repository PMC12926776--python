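"""Figure and table rendering for completed runs.

Conventions follow standard decoding-paper style: accuracy timecourses
with a dashed chance line at 0.5 and significant clusters underlined;
Bayes-factor panels on a log scale with dotted bands at 3 and 1/3
marking the inconclusive zone; topographic maps as position-colored
scatter over the montage layout; generalization matrices with
significance contours.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .montage import ElectrodeMontage

__all__ = ["plot_timecourse", "plot_bf_timecourse", "plot_topography",
           "plot_generalization_matrix", "plot_frequency_profile",
           "make_report"]


def plot_timecourse(times: np.ndarray, subject_values: np.ndarray,
                    significant: np.ndarray | None = None,
                    ax=None, chance: float = 0.5):
    """Group-mean accuracy with SEM band, chance line and cluster underline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    mean = subject_values.mean(axis=0)
    sem = subject_values.std(axis=0, ddof=1) / np.sqrt(subject_values.shape[0])
    ax.fill_between(times, mean - sem, mean + sem, alpha=0.3)
    ax.plot(times, mean)
    ax.axhline(chance, linestyle="--", color="k", linewidth=0.8)
    if significant is not None and significant.any():
        y = chance - 0.02
        ax.plot(times[significant], np.full(significant.sum(), y), ".",
                markersize=3, color="C3")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("accuracy")
    return ax


def plot_bf_timecourse(times: np.ndarray, bf10: np.ndarray, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.semilogy(times, bf10)
    ax.axhline(3.0, linestyle=":", color="k", linewidth=0.8)
    ax.axhline(1 / 3.0, linestyle=":", color="k", linewidth=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("BF10")
    return ax


def plot_topography(montage: ElectrodeMontage, values: np.ndarray, ax=None,
                    vmin: float | None = None, vmax: float | None = None):
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    sc = ax.scatter(montage.positions[:, 0], montage.positions[:, 1],
                    c=values, s=180, cmap="RdBu_r", vmin=vmin, vmax=vmax,
                    edgecolors="k", linewidths=0.5)
    circle = plt.Circle((0, 0), 1.05, fill=False, color="k", linewidth=0.8)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax


def plot_generalization_matrix(train_times: np.ndarray, test_times: np.ndarray,
                               mean_values: np.ndarray,
                               significant: np.ndarray | None = None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.pcolormesh(test_times, train_times, mean_values, cmap="YlOrRd",
                       vmin=0.5)
    if significant is not None and significant.any():
        ax.contour(test_times, train_times, significant.astype(float),
                   levels=[0.5], colors="k", linewidths=1.0)
    ax.set_xlabel("test time (ms)")
    ax.set_ylabel("train time (ms)")
    plt.colorbar(im, ax=ax, label="accuracy")
    return ax


def plot_frequency_profile(freqs: np.ndarray, profile: np.ndarray, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(freqs, profile)
    ax.axhline(0.5, linestyle="--", color="k", linewidth=0.8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("mean accuracy")
    return ax


def make_report(run_dir: str | Path) -> list[Path]:
    """Render summary figures for a completed pipeline run directory."""
    import pandas as pd

    run_dir = Path(run_dir)
    figdir = run_dir / "figures"
    figdir.mkdir(exist_ok=True)
    written: list[Path] = []

    tc_path = run_dir / "within_timecourse.csv"
    if not tc_path.exists():
        raise FileNotFoundError(f"missing artifact {tc_path}; run the pipeline first")
    tc = pd.read_csv(tc_path, comment="#")
    for task, sub in tc.groupby("task"):
        fig, axes = plt.subplots(1, 2, figsize=(10, 3))
        times = sub["time_ms"].to_numpy()
        axes[0].plot(times, sub["mean_accuracy"])
        axes[0].axhline(0.5, linestyle="--", color="k", linewidth=0.8)
        sig = sub["significant"].to_numpy(dtype=bool)
        if sig.any():
            axes[0].plot(times[sig], np.full(sig.sum(), 0.48), ".",
                         markersize=3, color="C3")
        axes[0].set_title(f"{task}: accuracy")
        axes[0].set_xlabel("time (ms)")
        axes[1].semilogy(times, sub["bf10"])
        axes[1].axhline(3, linestyle=":", color="k")
        axes[1].axhline(1 / 3, linestyle=":", color="k")
        axes[1].set_title(f"{task}: BF10")
        axes[1].set_xlabel("time (ms)")
        fig.tight_layout()
        p = figdir / f"within_{task}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
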