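"""Behavioral summaries: condition means, ANT network effects, inference.

The three attention-network scores are RT contrasts: alerting = no-cue
minus double-cue, orienting = center-cue minus time-space-cue, conflict =
incongruent minus congruent.  Cell means default to correct trials only.
Error bars for within-subject condition contrasts use the
Cousineau-normalised SEM with the Morey bias correction; group contrasts
use Welch's t, within-participant contrasts a paired t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "condition_summaries",
    "ant_effects",
    "within_subject_sem",
    "group_comparison",
    "paired_comparison",
    "plot_condition_bars",
]


def condition_summaries(trials: pd.DataFrame, by=("cue_condition",),
                        correct_only: bool = True) -> pd.DataFrame:
    """Per-cell accuracy and mean RT (with between-participant SEM).

    ``trials`` must hold columns ``correct``, ``rt`` (seconds),
    ``censored`` and the grouping columns in ``by``.  RT means use correct
    trials only unless ``correct_only=False``.  Cells with a single
    observation get SEM 0 and ``sem_defined=False``.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    by = list(by)
    ok = ~trials["censored"].astype(bool)
    t = trials[ok]
    rows = []
    for key, cell in t.groupby(by, sort=False, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        rt_sel = cell[cell["correct"] == 1] if correct_only else cell
        rt = rt_sel["rt"].to_numpy(dtype=float)
        n_rt = len(rt)
        rows.append({
            **dict(zip(by, key)),
            "n_trials": len(cell),
            "accuracy": float(cell["correct"].mean()),
            "mean_rt": float(rt.mean()) if n_rt else np.nan,
            "sem_rt": float(rt.std(ddof=1) / np.sqrt(n_rt)) if n_rt > 1 else 0.0,
            "sem_defined": n_rt > 1,
            "missing": n_rt == 0,
        })
    return pd.DataFrame(rows)


def _cell_means(trials, col, correct_only=True):
    ok = ~trials["censored"].astype(bool)
    t = trials[ok]
    if correct_only:
        t = t[t["correct"] == 1]
    return t.pivot_table(index="participant_id", columns=col, values="rt",
                         aggfunc="mean", observed=True)


def ant_effects(trials_or_means, correct_only: bool = True) -> pd.DataFrame:
    """Per-participant alerting, orienting and conflict effects (seconds).

    Accepts either a trial table (with ``participant_id``,
    ``cue_condition``, ``congruency``, ``correct``, ``rt``, ``censored``)
    or a pre-computed wide table of per-participant cell mean RTs whose
    columns include the needed cue/congruency levels.
    """
    if isinstance(trials_or_means, pd.DataFrame) and "rt" in trials_or_means:
        cue = _cell_means(trials_or_means, "cue_condition", correct_only)
        cong = _cell_means(trials_or_means, "congruency", correct_only)
        means = cue.join(cong)
    else:
        means = trials_or_means
    needed = ("no_cue", "double_cue", "center_cue", "time_space_cue",
              "incongruent", "congruent")
    missing = [c for c in needed if c not in means.columns or means[c].isna().any()]
    if missing:
        raise ValueError(f"missing cell means for: {missing}")
    return pd.DataFrame({
        "alerting": means["no_cue"] - means["double_cue"],
        "orienting": means["center_cue"] - means["time_space_cue"],
        "conflict": means["incongruent"] - means["congruent"],
    })


def within_subject_sem(cell_means: pd.DataFrame) -> pd.Series:
    """Within-subject SEM per cell (Cousineau normalisation, Morey factor).

    ``cell_means`` is participants x cells.  Each participant's mean is
    subtracted and the grand mean added back before taking the SEM, which
    removes between-participant offsets; the Morey factor
    sqrt(C / (C - 1)) corrects the resulting variance deflation.
    """
    m = cell_means.to_numpy(dtype=float)
    n, c = m.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if c < 2:
        raise ValueError("need at least 2 cells")
    normalized = m - m.mean(axis=1, keepdims=True) + m.mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    morey = np.sqrt(c / (c - 1.0))
    return pd.Series(sem * morey, index=cell_means.columns, name="within_sem")


@dataclass
class ComparisonResult:
    """Effect estimate with test statistics."""

    estimate: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    degenerate: bool = False  # zero-variance inputs


def _from_ttest(estimate, res, degenerate):
    ci = res.confidence_interval(0.95)
    return ComparisonResult(
        estimate=float(estimate), ci_low=float(ci.low), ci_high=float(ci.high),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        degenerate=degenerate)


def group_comparison(values, groups) -> ComparisonResult:
    """Welch two-sample comparison of a per-participant statistic.

    ``groups`` must contain exactly two labels; the estimate is
    mean(first) - mean(second) in order of appearance.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    x = values[groups == levels[0]]
    y = values[groups == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    degenerate = x.std() == 0.0 and y.std() == 0.0
    if degenerate:
        est = float(x.mean() - y.mean())
        return ComparisonResult(estimate=est, ci_low=est, ci_high=est,
                                t=np.nan, df=np.nan,
                                p=1.0 if est == 0.0 else 0.0, degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=False)
    return _from_ttest(x.mean() - y.mean(), res, degenerate)


def paired_comparison(x, y) -> ComparisonResult:
    """Paired comparison of two within-participant conditions (x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = x - y
    if d.std() == 0.0:
        est = float(d.mean())
        return ComparisonResult(estimate=est, ci_low=est, ci_high=est,
                                t=np.nan, df=np.nan,
                                p=1.0 if est == 0.0 else 0.0, degenerate=True)
    res = stats.ttest_rel(x, y)
    return _from_ttest(d.mean(), res, False)


def plot_condition_bars(means, sems=None, ylabel="", title="", ax=None):
    """Bar chart of condition means with error bars (requires matplotlib).

    ``means`` is a Series indexed by condition; ``sems`` an optional
    Series of matching error-bar half-heights (e.g. from
    :func:`within_subject_sem`).  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(means) + 1, 3))
    yerr = None if sems is None else sems.reindex(means.index).to_numpy()
    ax.bar(range(len(means)), means.to_numpy(), yerr=yerr, capsize=3,
           color="0.6", edgecolor="0.2")
    ax.set_xticks(range(len(means)))
    ax.set_xticklabels([str(i).replace("_", " ") for i in means.index],
                       rotation=30, ha="right")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    return ax
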