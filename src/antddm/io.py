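"""Trial-table and results file formats.

Trial tables are comma-delimited text with the exact header
``participant_id,group,session,block,trial,cue_condition,congruency,correct,rt_ms,censored``;
RTs are stored as integer milliseconds on disk and converted to seconds
(column ``rt``) in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CONGRUENCY_LEVELS, CUE_LEVELS, GROUP_LEVELS

__all__ = ["TRIAL_COLUMNS", "TrialTableError", "read_trials", "write_trials",
           "write_results"]

TRIAL_COLUMNS = ("participant_id", "group", "session", "block", "trial",
                 "cue_condition", "congruency", "correct", "rt_ms", "censored")

_SESSIONS = ("pre", "post")


class TrialTableError(ValueError):
    """Malformed trial table (bad header, vocabulary or values)."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; adds ``rt`` in seconds.

    Errors name the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    if tuple(df.columns) != TRIAL_COLUMNS:
        raise TrialTableError(
            f"{path}: header must be {','.join(TRIAL_COLUMNS)}, "
            f"got {','.join(df.columns)}")

    def _bad_rows(mask, what):
        rows = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
        raise TrialTableError(f"{path}: {what} in row(s) {rows[:10]}")

    for col, vocab in (("group", GROUP_LEVELS), ("session", _SESSIONS),
                       ("cue_condition", CUE_LEVELS),
                       ("congruency", CONGRUENCY_LEVELS)):
        bad = ~df[col].isin(vocab)
        if bad.any():
            _bad_rows(bad, f"unknown {col} label")
    for col in ("block", "trial", "correct", "rt_ms", "censored"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise TrialTableError(f"{path}: column {col} must be numeric")
    if not df["correct"].isin((0, 1)).all():
        _bad_rows(~df["correct"].isin((0, 1)), "correct flag not 0/1")
    if not df["censored"].isin((0, 1)).all():
        _bad_rows(~df["censored"].isin((0, 1)), "censored flag not 0/1")
    bad_rt = (df["rt_ms"] <= 0) & (df["censored"] == 0)
    if bad_rt.any():
        _bad_rows(bad_rt, "nonpositive rt_ms on uncensored trial")
    df = df.copy()
    df["rt"] = df["rt_ms"].astype(float) / 1000.0
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (expects ``rt`` in seconds or ``rt_ms``)."""
    df = trials.copy()
    if "rt_ms" not in df:
        df["rt_ms"] = np.rint(df["rt"] * 1000.0).astype(int)
    df["correct"] = df["correct"].astype(int)
    df["censored"] = df["censored"].astype(int)
    df[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def _params_frame(fits: dict) -> pd.DataFrame:
    """Flatten {(participant, analysis, scheme): FitResult} to a table."""
    rows = []
    for (pid, analysis, scheme_name), fit in fits.items():
        for cond, p in fit.params.items():
            rows.append({
                "participant_id": pid, "analysis": analysis,
                "model": scheme_name, "condition": cond,
                "a": p.a, "v": p.v, "eta": p.eta, "ter": p.ter,
                "objective": fit.objective, "k": fit.n_free_parameters,
                "n_trials": fit.n_trials_total, "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def write_results(fits: dict, comparisons: pd.DataFrame | None,
                  summaries: pd.DataFrame | None, outdir) -> list:
    """Write parameter estimates, best-model counts and behavior tables.

    ``fits`` maps (participant_id, analysis, scheme_name) -> FitResult;
    ``comparisons`` is a best-model count table (schemes x groups);
    ``summaries`` a behavioral summary table.  Returns the paths written.
    Empty inputs yield headers-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    params = _params_frame(fits) if fits else pd.DataFrame(
        columns=["participant_id", "analysis", "model", "condition",
                 "a", "v", "eta", "ter", "objective", "k", "n_trials",
                 "converged"])
    p1 = outdir / "parameter_estimates.csv"
    params.to_csv(p1, index=False)
    written.append(p1)
    if comparisons is not None:
        p2 = outdir / "best_model_counts.csv"
        comparisons.to_csv(p2, index_label="model")
        written.append(p2)
    if summaries is not None:
        p3 = outdir / "behavior_summaries.csv"
        summaries.to_csv(p3, index=False)
        written.append(p3)
    return written
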