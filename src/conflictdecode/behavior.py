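"""Behavioral pipeline: screening, per-condition summaries, conflict
effects, paired tests, and cross-task correlations of conflict effects.

Group statistics are computed on subject-level means (standard
repeated-measures practice): trials are first aggregated within subject
and condition, then the group mean and between-subject SD summarize the
subject means.  Conflict effects are defined as non-conflict minus
conflict, for both accuracy and response time — positive accuracy
effects and negative RT effects are the canonical conflict costs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import EffectSummary, effect_summary
from .preprocess import ScreeningRules

__all__ = ["screen_table", "summarize_behavior", "conflict_effects",
           "condition_tests", "cross_task_correlations"]


def screen_table(table: pd.DataFrame,
                 rules: ScreeningRules | None = None) -> pd.DataFrame:
    """Apply the RT screening rules to a trial table (all tasks at once)."""
    rules = rules or ScreeningRules()
    rt = table["rt_ms"].to_numpy(dtype=float)
    rt_max = table["task"].map(rules.rt_max).to_numpy(dtype=float)
    keep = np.isfinite(rt) & (rt >= rules.premature_ms) & (rt <= rt_max)
    if not rules.require_response:
        keep |= ~np.isfinite(rt)
    if rules.correct_only:
        keep &= table["correct"].to_numpy() == 1
    return table.loc[keep].reset_index(drop=True)


def summarize_behavior(table: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level and group-level per-condition summaries.

    Returns ``(subject_summary, group_summary)``.  The subject summary has
    one row per subject x task x condition with mean accuracy and mean RT
    (RT over responded trials); the group summary aggregates the subject
    means (mean and between-subject SD).  Subjects with no valid trial in
    a cell are absent from that cell.
    """
    grouped = table.groupby(["subject", "task", "condition"], sort=True)
    subject = grouped.agg(
        accuracy=("correct", "mean"),
        rt_ms=("rt_ms", "mean"),
        n_trials=("correct", "size"),
    ).reset_index()
    group = subject.groupby(["task", "condition"], sort=True).agg(
        mean_accuracy=("accuracy", "mean"),
        sd_accuracy=("accuracy", lambda v: v.std(ddof=1)),
        mean_rt_ms=("rt_ms", "mean"),
        sd_rt_ms=("rt_ms", lambda v: v.std(ddof=1)),
        n_subjects=("subject", "nunique"),
    ).reset_index()
    return subject, group


def conflict_effects(subject_summary: pd.DataFrame) -> pd.DataFrame:
    """Per subject x task conflict effects (non-conflict minus conflict)."""
    wide = subject_summary.pivot_table(
        index=["subject", "task"], columns="condition",
        values=["accuracy", "rt_ms"])
    need = [("accuracy", "conflict"), ("accuracy", "nonconflict"),
            ("rt_ms", "conflict"), ("rt_ms", "nonconflict")]
    wide = wide.dropna(subset=[c for c in need if c in wide.columns])
    out = pd.DataFrame({
        "d_accuracy": wide[("accuracy", "nonconflict")] - wide[("accuracy", "conflict")],
        "d_rt_ms": wide[("rt_ms", "nonconflict")] - wide[("rt_ms", "conflict")],
    }).reset_index()
    return out


def condition_tests(subject_summary: pd.DataFrame,
                    ) -> dict[tuple[str, str], EffectSummary]:
    """Paired conflict vs non-conflict tests per task and measure.

    Keys are ``(task, measure)`` with measure in {"accuracy", "rt_ms"};
    the comparison is conflict minus non-conflict (so conflict costs give
    negative accuracy differences and positive RT differences, matching
    the conventional reporting direction).
    """
    out = {}
    for task, sub in subject_summary.groupby("task"):
        wide = sub.pivot_table(index="subject", columns="condition",
                               values=["accuracy", "rt_ms"]).dropna()
        for measure in ("accuracy", "rt_ms"):
            out[(task, measure)] = effect_summary(
                wide[(measure, "conflict")].to_numpy(),
                wide[(measure, "nonconflict")].to_numpy())
    return out


def cross_task_correlations(effects: pd.DataFrame, measure: str = "d_rt_ms",
                            ) -> pd.DataFrame:
    """Spearman correlations of conflict effects across task pairs.

    Returns a tidy frame with one row per unordered task pair: rho
    (midrank ties), two-sided p via the t approximation, and the number
    of complete subject pairs.  Pairs with fewer than 3 complete subjects
    or a constant column are flagged with NaN rho.
    """
    wide = effects.pivot_table(index="subject", columns="task", values=measure)
    tasks = list(wide.columns)
    rows = []
    for i, a in enumerate(tasks):
        for b in tasks[i + 1:]:
            pair = wide[[a, b]].dropna()
            n = len(pair)
            if n < 3 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
                rows.append({"task_a": a, "task_b": b, "rho": np.nan,
                             "p": np.nan, "n": n})
                continue
            rho, p = stats.spearmanr(pair[a], pair[b])
            rows.append({"task_a": a, "task_b": b, "rho": float(rho),
                         "p": float(p), "n": n})
    return pd.DataFrame(rows)
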