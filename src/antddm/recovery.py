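"""Parameter-, group- and model-recovery protocols.

These experiments generate trials from the condition/group parameter
defaults (the values the analysis is designed to detect), run the
quantile-multinomial fit, and compare estimates with the generating truth.
They use the inflated-trials mode (2,000 trials per condition by default)
because the 94-trial ANT blocks are far too small for tight recovery.

In the parameter- and group-recovery fits, the non-decision time is held
at its generating value (0.30 s) rather than estimated: the generating
parameters put accuracy at ceiling, where the five correct-RT quantiles
leave a near-flat trade-off between threshold and non-decision time (the
Fisher information is close to singular along that direction), so
threshold recovery is only meaningful with Ter known.  Model recovery, in
contrast, fits all four candidate schemes exactly as the method would be
applied to real data (Ter estimated wherever a scheme frees or shares it).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ddm import DDMParams
from .model_space import SCHEMES, fit_all_models
from .quantile_fit import FitConfig, fit_participant
from .synthetic import (
    CONGRUENCY_PARAMS,
    CUE_PARAMS,
    GROUP_THRESHOLD,
    TER_DEFAULT,
    generate_condition_trials,
)

__all__ = [
    "recover_condition_parameters",
    "recover_group_thresholds",
    "model_recovery",
    "model_recovery_truth",
    "type1_error_rate",
]

_RECOVERY_SCHEME = SCHEMES[0]  # vary a, eta, v; Ter common


def _truth_params(analysis):
    src = CONGRUENCY_PARAMS if analysis == "congruency" else CUE_PARAMS
    return {lab: DDMParams.symmetric(a=g["a"], v=g["v"], ter=TER_DEFAULT,
                                     eta=g["eta"])
            for lab, g in src.items()}


def _seed_for(seed, *path):
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0]
               % (2**31 - 1))


def recover_condition_parameters(analysis="congruency", n_seeds=20,
                                 n_per_condition=2000, seed=0, dt=1e-4,
                                 config: FitConfig | None = None) -> dict:
    """Median recovered (a, v, eta) per condition over ``n_seeds`` replicates.

    Returns {"truth": {...}, "median": {...}, "per_seed": {...},
    "n_trials_total": int}.
    """
    truth = _truth_params(analysis)
    base_cfg = config or FitConfig(fix_ter=TER_DEFAULT)
    est = {lab: {"a": [], "v": [], "eta": []} for lab in truth}
    for k in range(n_seeds):
        datasets = generate_condition_trials(
            truth, n_per_condition, seed=_seed_for(seed, 1, k), dt=dt)
        cfg = dataclasses.replace(base_cfg, jitter_seed=_seed_for(seed, 2, k))
        fit = fit_participant(datasets, _RECOVERY_SCHEME, cfg)
        for lab, p in fit.params.items():
            est[lab]["a"].append(p.a)
            est[lab]["v"].append(p.v)
            est[lab]["eta"].append(p.eta)
    return {
        "analysis": analysis,
        "truth": {lab: {"a": p.a, "v": p.v, "eta": p.eta}
                  for lab, p in truth.items()},
        "median": {lab: {k: float(np.median(v)) for k, v in d.items()}
                   for lab, d in est.items()},
        "per_seed": est,
        "n_trials_total": n_seeds * n_per_condition * len(truth),
    }


def recover_group_thresholds(n_per_group=20, n_per_condition=2000, seed=0,
                             cv=0.10, dt=1e-4,
                             config: FitConfig | None = None) -> dict:
    """Cohort recovery of the meditator/control group-mean thresholds.

    Each participant's generating parameters are the congruency-analysis
    condition parameters re-centred on their group's threshold (meditators
    express the congruency modulation more strongly, controls less, as in
    the cell-parameter composition), with multiplicative normal
    between-participant jitter of coefficient of variation ``cv``.  Each
    participant is fitted with the {a, eta, v} scheme and summarised by
    the mean threshold over conditions; group means of those are compared
    with the generating 0.25 / 0.20.
    """
    from .synthetic import GROUP_CONGRUENCY_GAIN

    base_cfg = config or FitConfig(fix_ter=TER_DEFAULT)
    a_mean = float(np.mean([g["a"] for g in CONGRUENCY_PARAMS.values()]))
    rng = np.random.default_rng(_seed_for(seed, 3))
    recovered = {g: [] for g in GROUP_THRESHOLD}
    generating = {g: [] for g in GROUP_THRESHOLD}
    i = 0
    for group, base_a in GROUP_THRESHOLD.items():
        gain = GROUP_CONGRUENCY_GAIN[group]
        for _ in range(n_per_group):
            i += 1
            mult = {nm: max(float(rng.normal(1.0, cv)), 0.2)
                    for nm in ("a", "v", "eta")}
            truth = {}
            for lab, g in CONGRUENCY_PARAMS.items():
                a_i = (base_a + gain * (g["a"] - a_mean)) * mult["a"]
                truth[lab] = DDMParams.symmetric(
                    a=a_i, v=g["v"] * mult["v"], ter=TER_DEFAULT,
                    eta=g["eta"] * mult["eta"])
            generating[group].append(
                float(np.mean([p.a for p in truth.values()])))
            datasets = generate_condition_trials(
                truth, n_per_condition, seed=_seed_for(seed, 4, i), dt=dt)
            cfg = dataclasses.replace(base_cfg, jitter_seed=_seed_for(seed, 5, i))
            fit = fit_participant(datasets, _RECOVERY_SCHEME, cfg)
            recovered[group].append(
                float(np.mean([p.a for p in fit.params.values()])))
    return {
        "truth_group_mean": {g: float(v) for g, v in GROUP_THRESHOLD.items()},
        "generating_mean": {g: float(np.mean(v)) for g, v in generating.items()},
        "recovered_mean": {g: float(np.mean(v)) for g, v in recovered.items()},
        "recovered": recovered,
        "n_participants": 2 * n_per_group,
        "n_trials_total": 2 * n_per_group * n_per_condition
        * len(CONGRUENCY_PARAMS),
    }


#: observed task accuracies per congruency condition; the model-recovery
#: drifts are calibrated to reproduce these
MODEL_RECOVERY_ACCURACY = {"congruent": 0.99, "neutral": 0.99,
                           "incongruent": 0.94}


def model_recovery_truth() -> dict:
    """Generating parameters for the model-recovery experiment.

    Thresholds, drift variabilities and Ter are the congruency-analysis
    values; the drift rates are solved (per condition) so that the model's
    choice probability equals the task's observed accuracy.  At the
    condition-mean parameter estimates themselves accuracy sits at
    numerical ceiling, where a condition-wise {a, eta} model can absorb
    any drift-rate difference and the sharing schemes become statistically
    indistinguishable; condition effects are only "strong" in the
    model-recovery sense when the error rate carries the drift signal.
    """
    from scipy.optimize import brentq

    from .ddm import choice_probability

    out = {}
    for lab, g in CONGRUENCY_PARAMS.items():
        acc = MODEL_RECOVERY_ACCURACY[lab]

        def miss(v):
            p = DDMParams.symmetric(a=g["a"], v=v, ter=TER_DEFAULT,
                                    eta=g["eta"])
            return choice_probability(p, "upper") - acc

        v = brentq(miss, 0.02, 2.0, xtol=1e-8)
        out[lab] = DDMParams.symmetric(a=g["a"], v=v, ter=TER_DEFAULT,
                                       eta=g["eta"])
    return out


def model_recovery(n_seeds=20, n_per_condition=2000, seed=0, dt=1e-4,
                   config: FitConfig | None = None) -> dict:
    """How often BIC selects the generating {a, eta, v} sharing scheme.

    Data are generated under the {a, eta, v} scheme (a, v and eta differ
    across conditions, Ter shared) with accuracy-calibrated drifts (see
    :func:`model_recovery_truth`); all four candidate schemes are fitted
    per replicate exactly as on real data and the BIC winner counted.
    Simulation uses a long censoring horizon so the slower error-prone
    conditions are not truncated.
    """
    truth = model_recovery_truth()
    base_cfg = config or FitConfig()
    counts = {s.name: 0 for s in SCHEMES}
    for k in range(n_seeds):
        datasets = generate_condition_trials(
            truth, n_per_condition, seed=_seed_for(seed, 6, k), dt=dt,
            max_time=6.0)
        cfg = dataclasses.replace(base_cfg, jitter_seed=_seed_for(seed, 7, k))
        comp = fit_all_models(datasets, cfg)
        counts[comp.best] += 1
    return {
        "generating_scheme": _RECOVERY_SCHEME.name,
        "counts": counts,
        "selection_rate": counts[_RECOVERY_SCHEME.name] / n_seeds,
        "n_seeds": n_seeds,
    }


def type1_error_rate(n_reps=1000, n_per_group=20, seed=0, alpha=0.05,
                     cv=0.10) -> dict:
    """False-positive rate of the group comparison under a null generator.

    Both groups' per-participant thresholds are drawn from the same
    distribution (no group difference); the Welch comparison is applied
    per replicate and the rejection rate at ``alpha`` returned.
    """
    from .behavior import group_comparison

    rng = np.random.default_rng(_seed_for(seed, 8))
    null_mean = float(np.mean(list(GROUP_THRESHOLD.values())))
    rejections = 0
    for _ in range(n_reps):
        vals = rng.normal(null_mean, cv * null_mean, size=2 * n_per_group)
        groups = np.array(["meditator"] * n_per_group
                          + ["control"] * n_per_group)
        res = group_comparison(vals, groups)
        if res.p < alpha:
            rejections += 1
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
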