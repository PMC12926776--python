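"""End-to-end orchestration: simulate -> behavior -> decode -> stats -> report.

A :class:`RunConfig` gathers every stage's settings plus a single global
seed; per-stage seeds are derived by hashing ``"<seed>:<stage>"`` with
SHA-256 (mod 2^31), so any stage can be rerun in isolation and still
reproduce.  Every run directory receives a ``manifest.json`` naming the
package version, the config hash, the seed, and the SHA-256 of every
numeric artifact — two runs with identical config and seed produce
byte-identical artifacts and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (condition_tests, conflict_effects,
                       cross_task_correlations, screen_table,
                       summarize_behavior)
from .cross import cross_task_matrix
from .epochs import save_epochs, write_trial_table
from .inference import (TfceParams, bf_timecourse, montecarlo_cluster_stat,
                        stelzer_null)
from .preprocess import ScreeningRules
from .synth import SynthConfig, TaskRecipe, demo_config, generate_dataset
from .within import (FrequencyFeatureConfig, decode_frequency,
                     decode_timecourse, searchlight_frequency)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config",
           "config_hash"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    synth: SynthConfig
    out_dir: str = "run"
    seed: int = 0
    lam: float = 0.01
    k_folds: int = 10
    label_type: str = "condition"
    fconfig: FrequencyFeatureConfig = field(default_factory=FrequencyFeatureConfig)
    tfce: TfceParams = field(default_factory=lambda: TfceParams(n_iter=1000))
    screening: ScreeningRules = field(default_factory=ScreeningRules)
    n_perm_subject: int = 100
    n_null_draws: int = 10_000
    exclude_from_cross: tuple[str, ...] = ()
    run_frequency: bool = True
    run_cross: bool = True
    save_epochs: bool = False


def config_hash(config: RunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj
    payload = enc(config)
    payload.pop("out_dir", None)  # where results land is not configuration
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    The file mirrors the dataclass layout; the ``synth`` section either
    gives ``demo: true`` (plus overrides for the built-in demo recipe) or
    lists ``tasks`` explicitly as mappings of TaskRecipe fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    synth_raw = dict(raw.pop("synth", {}))
    if synth_raw.pop("demo", False):
        synth = demo_config(**synth_raw)
    else:
        tasks = tuple(TaskRecipe(**t) for t in synth_raw.pop("tasks", []))
        synth = SynthConfig(tasks=tasks, **synth_raw)
    kwargs: dict = {"synth": synth}
    if "fconfig" in raw:
        kwargs["fconfig"] = FrequencyFeatureConfig(**raw.pop("fconfig"))
    if "tfce" in raw:
        kwargs["tfce"] = TfceParams(**raw.pop("tfce"))
    if "screening" in raw:
        kwargs["screening"] = ScreeningRules(**raw.pop("screening"))
    if "exclude_from_cross" in raw:
        kwargs["exclude_from_cross"] = tuple(raw.pop("exclude_from_cross"))
    kwargs.update(raw)
    return RunConfig(**kwargs)


def _provenance_header(config: RunConfig) -> str:
    return (f"# conflictdecode {__version__} | config {config_hash(config)} | "
            f"seed {config.seed} | lam {config.lam}\n")


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Partial outputs are retained on failure; the failing stage is named
    in the raised :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    stage = "simulate"
    try:
        data = generate_dataset(dataclasses.replace(
            config.synth, seed=stage_seed(config.seed, "simulate")))
        table_path = out / "trial_table.tsv"
        write_trial_table(data.trial_table, table_path)
        artifacts.append(table_path)
        if config.save_epochs:
            for (subj, task), es in data.epochs.items():
                npy, meta = save_epochs(es, out / "epochs" / f"{subj}_{task}")
                artifacts += [npy, meta]

        stage = "behavior"
        screened = screen_table(data.trial_table, config.screening)
        subj_sum, group_sum = summarize_behavior(screened)
        effects = conflict_effects(subj_sum)
        tests = condition_tests(subj_sum)
        tests_df = pd.DataFrame([
            {"task": task, "measure": measure, "n": s.n, "df": s.df,
             "mean_diff": s.mean_diff, "t": s.t, "p": s.p, "d_av": s.d_av,
             "ci_low": s.ci_low, "ci_high": s.ci_high, "bf10": s.bf10}
            for (task, measure), s in sorted(tests.items())])
        corr = pd.concat([
            cross_task_correlations(effects, "d_rt_ms").assign(measure="d_rt_ms"),
            cross_task_correlations(effects, "d_accuracy").assign(measure="d_accuracy"),
        ], ignore_index=True)
        for name, df in [("behavior_subject.csv", subj_sum),
                         ("behavior_group.csv", group_sum),
                         ("conflict_effects.csv", effects),
                         ("condition_tests.csv", tests_df),
                         ("cross_task_correlations.csv", corr)]:
            p = out / name
            _write_csv(df, p, config)
            artifacts.append(p)

        stage = "decode_within"
        tasks = data.tasks
        subjects = data.subjects
        within_rows = []
        cluster_rows = []
        timecourses: dict[str, np.ndarray] = {}
        infer: dict[str, object] = {}
        seed_w = stage_seed(config.seed, "decode_within")
        for task in tasks:
            maps = []
            for si, subj in enumerate(subjects):
                es = data.epochs[(subj, task)]
                dm = decode_timecourse(es, lam=config.lam, k=config.k_folds,
                                       seed=seed_w + si,
                                       label_type=config.label_type)
                maps.append(dm.values)
            maps = np.asarray(maps)
            timecourses[task] = maps
            times = data.epochs[(subjects[0], task)].times
            ci = montecarlo_cluster_stat(
                maps, dataclasses.replace(
                    config.tfce, seed=stage_seed(config.seed, f"tfce:{task}")),
                axes=[times])
            infer[task] = ci
            bf = bf_timecourse(maps)
            for j, t_ms in enumerate(times):
                within_rows.append({
                    "task": task, "time_ms": t_ms,
                    "mean_accuracy": maps[:, j].mean(),
                    "t": ci.t_map[j], "p_corrected": ci.p_corrected[j],
                    "significant": bool(ci.significant[j]), "bf10": bf[j]})
            for c in ci.clusters:
                cluster_rows.append({"task": task,
                                     "start_ms": c["axis0_start"],
                                     "end_ms": c["axis0_end"],
                                     "n_cells": c["n_cells"],
                                     "peak_t": c["peak_stat"],
                                     "p_corrected": c["p_corrected"]})
        p = out / "within_timecourse.csv"
        _write_csv(pd.DataFrame(within_rows), p, config)
        artifacts.append(p)
        p = out / "within_clusters.csv"
        _write_csv(pd.DataFrame(
            cluster_rows, columns=["task", "start_ms", "end_ms", "n_cells",
                                   "peak_t", "p_corrected"]), p, config)
        artifacts.append(p)

        if config.run_frequency:
            stage = "decode_frequency"
            seed_f = stage_seed(config.seed, "decode_frequency")
            freq_rows = []
            for task in tasks:
                accs, perms, profiles = [], [], []
                for si, subj in enumerate(subjects):
                    es = data.epochs[(subj, task)]
                    accs.append(decode_frequency(
                        es, config.fconfig, lam=config.lam, k=config.k_folds,
                        seed=seed_f + si, label_type=config.label_type))
                    rng = np.random.default_rng(seed_f + 1000 + si)
                    subj_perms = []
                    for _ in range(config.n_perm_subject):
                        shuffled = es.copy()
                        perm = rng.permutation(es.n_trials)
                        shuffled.trials["condition"] = \
                            es.trials["condition"].to_numpy()[perm]
                        subj_perms.append(decode_frequency(
                            shuffled, config.fconfig, lam=config.lam,
                            k=config.k_folds, seed=seed_f + si,
                            label_type=config.label_type))
                    perms.append(subj_perms)
                    sl_map, profile, _ = searchlight_frequency(
                        es, config.fconfig, lam=config.lam, k=config.k_folds,
                        seed=seed_f + si, label_type=config.label_type)
                    profiles.append(profile)
                    bin_freqs = sl_map.axes["frequency"]
                null = stelzer_null(float(np.mean(accs)), np.asarray(perms),
                                    n_draws=config.n_null_draws,
                                    seed=stage_seed(config.seed, f"stelzer:{task}"))
                freq_rows.append({
                    "task": task, "mean_accuracy": null.observed,
                    "percentile": null.percentile,
                    "significant": null.significant,
                    "null_mean": float(null.group_draws.mean()),
                    "profile_peak_hz": float(bin_freqs[int(np.argmax(
                        np.mean(profiles, axis=0)))])})
            p = out / "frequency_decoding.csv"
            _write_csv(pd.DataFrame(freq_rows), p, config)
            artifacts.append(p)

        if config.run_cross:
            stage = "decode_cross"
            seed_c = stage_seed(config.seed, "decode_cross")
            cross_tasks = [t for t in tasks if t not in config.exclude_from_cross]
            cross_rows = []
            for a in cross_tasks:
                for b in cross_tasks:
                    if a == b:
                        continue
                    mats = []
                    for si, subj in enumerate(subjects):
                        gm = cross_task_matrix(
                            data.epochs[(subj, a)], data.epochs[(subj, b)],
                            lam=config.lam, seed=seed_c + si,
                            label_type=config.label_type)
                        mats.append(gm.values)
                    mats = np.asarray(mats)
                    t_a = data.epochs[(subjects[0], a)].times
                    t_b = data.epochs[(subjects[0], b)].times
                    ci = montecarlo_cluster_stat(
                        mats, dataclasses.replace(
                            config.tfce,
                            seed=stage_seed(config.seed, f"tfce:{a}->{b}")),
                        axes=[t_a, t_b])
                    cross_rows.append({
                        "train_task": a, "test_task": b,
                        "mean_accuracy": float(mats.mean()),
                        "max_mean_accuracy": float(mats.mean(axis=0).max()),
                        "n_significant_cells": int(ci.significant.sum()),
                        "n_clusters": len(ci.clusters),
                        "min_p_corrected": float(ci.p_corrected.min())})
            p = out / "cross_task.csv"
            _write_csv(pd.DataFrame(cross_rows), p, config)
            artifacts.append(p)

        stage = "manifest"
        manifest = {
            "package": "conflictdecode",
            "version": __version__,
            "config_hash": config_hash(config),
            "seed": config.seed,
            "lam": config.lam,
            "artifacts": {
                str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(artifacts)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - re-raise with the stage name
        raise StageError(stage, err) from err
    return out
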