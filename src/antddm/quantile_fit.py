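"""Quantile-based multinomial estimation of DDM parameters.

Observed RTs per condition are reduced to the 0.1/0.3/0.5/0.7/0.9
quantiles of the correct and error distributions; the model's probability
mass between those edges defines a multinomial likelihood, and Nelder-Mead
simplex search (multi-start) finds the parameters minimising
-2 log L summed over conditions ("quantile maximum probability
estimation").  A Pearson X^2 variant of the objective is available behind
a config switch.

Conditions with fewer than 11 errors keep a single collapsed error bin,
since near-ceiling accuracy leaves error quantiles undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import _fpt
from .ddm import DDMParams, _GH_X, _GH_W, _GL_X, _GL_W

__all__ = [
    "ConditionDataset",
    "RTQuantileSummary",
    "FitConfig",
    "FitResult",
    "FitFailedError",
    "DEFAULT_QUANTILES",
    "empirical_quantiles",
    "observed_bin_counts",
    "neg2_log_multinomial",
    "pearson_chi2",
    "ez_init",
    "fit_participant",
    "datasets_from_trials",
]

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)

#: minimum observations for per-quantile binning; below this the side
#: collapses to a single bin
MIN_FOR_QUANTILES = 11

PROB_FLOOR = 1e-10


class FitFailedError(RuntimeError):
    """All restarts violated domain constraints or failed to evaluate."""


@dataclass
class ConditionDataset:
    """Correct/error RTs (seconds) for one experimental condition."""

    label: str
    correct_rt: np.ndarray
    error_rt: np.ndarray
    n_censored: int = 0

    def __post_init__(self):
        self.correct_rt = np.asarray(self.correct_rt, dtype=float)
        self.error_rt = np.asarray(self.error_rt, dtype=float)
        if (self.correct_rt <= 0).any() or (self.error_rt <= 0).any():
            raise ValueError(f"condition {self.label!r}: RTs must be positive")

    @property
    def n_trials(self):
        return len(self.correct_rt) + len(self.error_rt)


@dataclass
class RTQuantileSummary:
    """Quantile edges and bin counts for one condition."""

    label: str
    quantile_probs: tuple
    correct_edges: np.ndarray | None  # None => single collapsed bin
    error_edges: np.ndarray | None
    correct_counts: np.ndarray
    error_counts: np.ndarray
    degenerate: bool = False  # tied edges detected

    @property
    def n_trials(self):
        return int(self.correct_counts.sum() + self.error_counts.sum())


@dataclass
class FitConfig:
    """Fitting options (quantiles, trimming, restarts, optimizer tolerances)."""

    quantile_probs: tuple = DEFAULT_QUANTILES
    trim_threshold: float = 0.150  # fast-guess cutoff, seconds
    objective: str = "multinomial"  # or "pearson"
    n_restarts: int = 5
    jitter: float = 0.2
    jitter_seed: int = 0
    maxiter: int = 2000
    xatol: float = 1e-4
    fatol: float = 1e-4
    s: float = 0.1
    sz: float = 0.0
    st: float = 0.0
    #: when set, the non-decision time is not estimated but held at this
    #: value (used by recovery studies where Ter is part of the generating
    #: design; the 5-quantile scheme leaves a near-flat a-Ter trade-off at
    #: ceiling accuracy, so recovery of a/v/eta is assessed with Ter known)
    fix_ter: float | None = None
    #: estimate starting-point and non-decision-time variability as
    #: parameters shared across conditions (instead of fixing them at the
    #: sz/st values above)
    estimate_sz_st: bool = False
    bounds_a: tuple = (0.06, 0.6)
    bounds_v: tuple = (0.01, 3.0)
    bounds_eta: tuple = (0.0, 0.5)
    bounds_sz: tuple = (0.0, 0.025)
    bounds_st: tuple = (0.0, 0.1)


@dataclass
class FitResult:
    """Best-fitting parameters for one participant under one sharing scheme."""

    params: dict  # condition label -> DDMParams
    objective: float
    n_trials_total: int
    n_free_parameters: int
    converged: bool
    restarts_used: int
    scheme: object = None  # SharingScheme, set by model_space helpers
    jitter_seed: int = 0


def empirical_quantiles(rts, quantile_probs=DEFAULT_QUANTILES):
    """Quantile edges by the type-7 (linear interpolation) convention."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot take quantiles of an empty sample")
    return np.quantile(rts, quantile_probs, method="linear")


def _side_summary(rts, quantile_probs):
    """Edges, counts and degeneracy flag for one response side."""
    n = len(rts)
    if n < MIN_FOR_QUANTILES:
        return None, np.array([n]), False
    edges = empirical_quantiles(rts, quantile_probs)
    if not np.all(np.diff(edges) > 0):
        # tied quantiles (e.g. many identical RTs): collapse the side
        return None, np.array([n]), True
    # right-closed bins: an RT exactly on an edge counts below it
    idx = np.searchsorted(edges, rts, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    return edges, counts, False


def observed_bin_counts(data: ConditionDataset,
                        quantile_probs=DEFAULT_QUANTILES) -> RTQuantileSummary:
    """Tabulate correct/error RTs into inter-quantile bins."""
    if data.n_trials == 0:
        raise ValueError(f"condition {data.label!r} has no trials")
    ce, cc, cdeg = _side_summary(data.correct_rt, quantile_probs)
    ee, ec, edeg = _side_summary(data.error_rt, quantile_probs)
    return RTQuantileSummary(
        label=data.label, quantile_probs=tuple(quantile_probs),
        correct_edges=ce, error_edges=ee,
        correct_counts=cc, error_counts=ec,
        degenerate=cdeg or edeg)


def neg2_log_multinomial(counts, probs, floor=PROB_FLOOR):
    """-2 * sum(n_i log p_i), the multinomial deviance kernel.

    The multinomial coefficient (a data-only constant) is dropped; the
    same convention must be used for every model being compared.
    """
    counts = np.asarray(counts, dtype=float)
    probs = np.maximum(np.asarray(probs, dtype=float), floor)
    if counts.shape != probs.shape:
        raise ValueError("counts and probabilities must share one bin structure")
    return float(-2.0 * np.sum(counts * np.log(probs)))


def pearson_chi2(counts, probs, floor=PROB_FLOOR):
    """Pearson X^2 between observed counts and model bin probabilities."""
    counts = np.asarray(counts, dtype=float)
    probs = np.maximum(np.asarray(probs, dtype=float), floor)
    n = counts.sum()
    expected = n * probs
    return float(np.sum((counts - expected) ** 2 / expected))


def ez_init(correct_rt, error_rt, s=0.1):
    """Moment-based starting values (a, v, Ter) from accuracy and correct-RT
    mean/variance, in the style of the EZ diffusion shortcut."""
    n = len(correct_rt) + len(error_rt)
    pc = len(correct_rt) / n
    pc = min(max(pc, 1.0 - (n - 0.5) / n), (n - 0.5) / n)  # edge correction
    # sorted summation keeps the heuristic invariant to trial order
    srt = np.sort(np.asarray(correct_rt, dtype=float))
    mrt = float(np.mean(srt))
    vrt = float(np.var(srt))
    vrt = max(vrt, 1e-4)
    L = math.log(pc / (1.0 - pc))
    if abs(L) < 1e-6:
        L = 1e-6
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = math.copysign(s * abs(x) ** 0.25, pc - 0.5)
    if abs(v) < 1e-3:
        v = 1e-3
    a = s * s * L / v
    a = min(max(a, 0.08), 0.5)
    y = -v * a / (s * s)
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    ter = mrt - mdt
    return a, v, ter


def _trim(data: ConditionDataset, threshold):
    """Drop fast guesses below the trimming threshold."""
    if threshold <= 0:
        return data
    return ConditionDataset(
        label=data.label,
        correct_rt=data.correct_rt[data.correct_rt >= threshold],
        error_rt=data.error_rt[data.error_rt >= threshold],
        n_censored=data.n_censored)


def _unpack(theta, scheme_free, n_cond, fix_ter=None):
    """theta -> per-condition dict of (a, v, eta, ter) values.

    Layout: for each parameter in canonical order (a, v, eta, ter), C
    entries if it varies across conditions, else one shared entry; a fixed
    Ter consumes no entries.
    """
    out = {}
    i = 0
    for name in ("a", "v", "eta", "ter"):
        if name == "ter" and fix_ter is not None:
            out[name] = np.repeat(fix_ter, n_cond)
        elif name in scheme_free:
            out[name] = theta[i:i + n_cond]
            i += n_cond
        else:
            out[name] = np.repeat(theta[i], n_cond)
            i += 1
    return out


def _pack_info(scheme_free, n_cond, inits, bounds_map, fix_ter=None):
    """Initial vector and bounds arrays matching the _unpack layout."""
    x0, lo, hi = [], [], []
    for name in ("a", "v", "eta", "ter"):
        if name == "ter" and fix_ter is not None:
            continue
        vals = inits[name]
        b = bounds_map[name]
        if name in scheme_free:
            for c in range(n_cond):
                x0.append(vals[c]); lo.append(b[0]); hi.append(b[1])
        else:
            x0.append(float(np.mean(vals))); lo.append(b[0]); hi.append(b[1])
    return np.array(x0), np.array(lo), np.array(hi)


def fit_participant(datasets, scheme, config: FitConfig | None = None) -> FitResult:
    """Estimate one participant's parameters under a sharing scheme.

    ``scheme`` must expose ``free`` (an iterable from {"a","v","eta","ter"}
    naming the parameters that vary across conditions) and, optionally,
    ``k(n_conditions)``.  Minimisation is Nelder-Mead with bounds, run from
    ``n_restarts`` jittered moment-heuristic starting points.
    """
    config = config or FitConfig()
    if len(datasets) < 1:
        raise ValueError("need at least one condition dataset")
    scheme_free = frozenset(getattr(scheme, "free", scheme))
    if not scheme_free <= {"a", "v", "eta", "ter"}:
        raise ValueError(f"unknown free parameters: {scheme_free}")
    if config.fix_ter is not None and "ter" in scheme_free:
        raise ValueError("cannot fix Ter while the scheme lets it vary")
    n_cond = len(datasets)
    trimmed = [_trim(d, config.trim_threshold) for d in datasets]
    summaries = [observed_bin_counts(d, config.quantile_probs) for d in trimmed]
    counts = [np.concatenate([s.correct_counts, s.error_counts]) for s in summaries]
    edges_c = [np.asarray(s.correct_edges if s.correct_edges is not None else [],
                          dtype=float) for s in summaries]
    edges_e = [np.asarray(s.error_edges if s.error_edges is not None else [],
                          dtype=float) for s in summaries]
    n_total = int(sum(s.n_trials for s in summaries))

    loss = neg2_log_multinomial if config.objective == "multinomial" else pearson_chi2
    if config.objective not in ("multinomial", "pearson"):
        raise ValueError(f"unknown objective {config.objective!r}")
    s_scale = config.s
    fix_ter = config.fix_ter
    est_var = config.estimate_sz_st

    def objective(theta):
        core = theta[:-2] if est_var else theta
        vals = _unpack(core, scheme_free, n_cond, fix_ter)
        sz, st = (theta[-2], theta[-1]) if est_var else (config.sz, config.st)
        total = 0.0
        for c in range(n_cond):
            a = vals["a"][c]; v = vals["v"][c]
            eta = vals["eta"][c]; ter = vals["ter"][c]
            z = 0.5 * a
            # keep the variability ranges inside the parameter domain
            sz_c = min(sz, 0.9 * z)
            st_c = min(st, ter)
            pc, pe = _fpt.bin_probs(
                edges_c[c], edges_e[c],
                v / s_scale, a / s_scale, z / s_scale,
                (eta if eta > 1e-10 else 0.0) / s_scale, sz_c / s_scale,
                ter, st_c, _GH_X, _GH_W, _GL_X, _GL_W)
            total += loss(counts[c], np.concatenate([pc, pe]))
        return total

    # moment-heuristic starting values per condition
    ez = [ez_init(d.correct_rt, d.error_rt, s_scale) if len(d.correct_rt) > 1
          else (0.2, 0.7, 0.3) for d in trimmed]
    min_edge = min((e[0] for e in edges_c if e.size), default=np.inf)
    min_rt = min(min(d.correct_rt.min() if len(d.correct_rt) else np.inf,
                     d.error_rt.min() if len(d.error_rt) else np.inf)
                 for d in trimmed)
    ter_hi = min(min_edge, min_rt) - 1e-3
    ter_hi = max(ter_hi, 0.06)
    bounds_map = {"a": config.bounds_a, "v": config.bounds_v,
                  "eta": config.bounds_eta, "ter": (0.05, ter_hi)}
    inits = {
        "a": [e[0] for e in ez],
        "v": [max(e[1], 0.05) for e in ez],
        "eta": [0.1] * n_cond,
        "ter": [min(max(e[2], 0.08), ter_hi - 1e-3) for e in ez],
    }
    x0, lo, hi = _pack_info(scheme_free, n_cond, inits, bounds_map, fix_ter)
    if est_var:
        x0 = np.concatenate([x0, [0.01, 0.02]])
        lo = np.concatenate([lo, [config.bounds_sz[0], config.bounds_st[0]]])
        hi = np.concatenate([hi, [config.bounds_sz[1], config.bounds_st[1]]])
    x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)

    rng = np.random.default_rng(config.jitter_seed)
    best = None
    n_ok = 0
    for r in range(config.n_restarts):
        if r == 0:
            start = x0
        else:
            start = x0 * (1.0 + config.jitter * rng.uniform(-1, 1, size=x0.shape))
            start = np.clip(start, lo + 1e-6, hi - 1e-6)
        try:
            res = minimize(objective, start, method="Nelder-Mead",
                           bounds=list(zip(lo, hi)),
                           options={"maxiter": config.maxiter,
                                    "maxfev": 4 * config.maxiter,
                                    "xatol": config.xatol,
                                    "fatol": config.fatol})
        except (FloatingPointError, ValueError):
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitFailedError(
            f"all {config.n_restarts} restarts failed for scheme {sorted(scheme_free)}")

    core = best.x[:-2] if est_var else best.x
    sz_hat, st_hat = ((float(best.x[-2]), float(best.x[-1])) if est_var
                      else (config.sz, config.st))
    vals = _unpack(core, scheme_free, n_cond, fix_ter)
    params = {}
    for c, s in enumerate(summaries):
        a_c = float(vals["a"][c])
        ter_c = float(vals["ter"][c])
        params[s.label] = DDMParams.symmetric(
            a=a_c, v=float(vals["v"][c]), ter=ter_c,
            eta=float(vals["eta"][c]),
            sz=min(sz_hat, 0.9 * 0.5 * a_c), st=min(st_hat, ter_c),
            s=s_scale)
    k = len(x0)
    return FitResult(
        params=params, objective=float(best.fun), n_trials_total=n_total,
        n_free_parameters=k, converged=bool(best.success), restarts_used=n_ok,
        scheme=scheme if hasattr(scheme, "free") else None,
        jitter_seed=config.jitter_seed)


def datasets_from_trials(trials, analysis="congruency", trim_threshold=0.0):
    """Split a trial table (DataFrame) into per-condition datasets.

    ``analysis`` selects the factor: "congruency" (3 conditions, collapsed
    over cues) or "cue" (4 conditions, collapsed over congruency).  The
    table needs columns ``congruency``/``cue_condition``, ``correct``,
    ``rt`` (seconds) and ``censored``.  Censored trials are excluded and
    counted.
    """
    from .synthetic import CONGRUENCY_LEVELS, CUE_LEVELS

    col, levels = (("congruency", CONGRUENCY_LEVELS) if analysis == "congruency"
                   else ("cue_condition", CUE_LEVELS))
    if analysis not in ("congruency", "cue"):
        raise ValueError(f"analysis must be 'congruency' or 'cue', got {analysis!r}")
    out = []
    for level in levels:
        sub = trials[trials[col] == level]
        ok = ~sub["censored"].astype(bool)
        sub_ok = sub[ok]
        rt = sub_ok["rt"].to_numpy(dtype=float)
        correct = sub_ok["correct"].to_numpy(dtype=bool)
        keep = rt >= trim_threshold if trim_threshold > 0 else np.ones(len(rt), bool)
        out.append(ConditionDataset(
            label=level,
            correct_rt=rt[keep & correct],
            error_rt=rt[keep & ~correct],
            n_censored=int((~ok).sum())))
    return out
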