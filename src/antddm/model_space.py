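"""The four condition-wise parameter-sharing models and BIC selection.

Each candidate model lets a subset of {a, v, eta, Ter} vary across the
conditions of an analysis while sharing the rest; the starting point is
fixed at z = a/2 and sz = st = 0 unless configured otherwise.  Candidates
are compared per participant by BIC = -2 log L + k ln(n), with n the total
trial count entering that analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .quantile_fit import FitConfig, FitFailedError, fit_participant

__all__ = [
    "SharingScheme",
    "ModelComparison",
    "SCHEMES",
    "build_model_space",
    "bic",
    "select_best",
    "fit_all_models",
    "best_model_counts",
]

_ALL_PARAMS = ("a", "v", "eta", "ter")


@dataclass(frozen=True)
class SharingScheme:
    """Which diffusion parameters vary across conditions."""

    name: str
    free: frozenset
    label: str  # display label in comparison tables

    def k(self, n_conditions: int) -> int:
        """Free-parameter count: one per condition for varying parameters,
        one overall for shared ones."""
        return len(self.free) * n_conditions + (len(_ALL_PARAMS) - len(self.free))


def _scheme(name, free, label):
    return SharingScheme(name=name, free=frozenset(free), label=label)


#: The four candidate models, in canonical (tie-break) order.
SCHEMES = (
    _scheme("a_eta_v", ("a", "eta", "v"), "vary a, eta, v"),
    _scheme("a_eta", ("a", "eta"), "vary a, eta"),
    _scheme("a_eta_v_ter", ("a", "eta", "v", "ter"), "vary a, eta, v, Ter"),
    _scheme("a_v_ter", ("a", "v", "ter"), "vary a, v, Ter"),
)


def build_model_space(n_conditions: int):
    """The four candidate sharing schemes (requires >= 2 conditions)."""
    if n_conditions < 2:
        raise ValueError("model comparison needs at least 2 conditions")
    return list(SCHEMES)


def bic(objective: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: objective (-2 log L) + k ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return objective + k * math.log(n)


@dataclass
class ModelComparison:
    """Per-model fits and BICs for one participant, with the winner."""

    fits: dict        # scheme name -> FitResult
    bics: dict        # scheme name -> BIC
    best: str         # winning scheme name
    delta_bic: dict   # scheme name -> BIC - min BIC


def select_best(fits) -> ModelComparison:
    """Choose the minimal-BIC model among fitted schemes.

    Ties go to the scheme with fewer free parameters, then to the
    canonical scheme order.  Failed fits (None entries) are excluded with
    a warning; if everything failed, raises FitFailedError.
    """
    order = {s.name: i for i, s in enumerate(SCHEMES)}
    valid = {}
    for fit in fits:
        if fit is None:
            continue
        if fit.scheme is None:
            raise ValueError("FitResult.scheme must be set for model selection")
        valid[fit.scheme.name] = fit
    if len(fits) != len(valid):
        warnings.warn(f"{len(fits) - len(valid)} failed fit(s) excluded "
                      "from model selection", stacklevel=2)
    if not valid:
        raise FitFailedError("no successful fits to compare")
    if len(valid) < 2:
        warnings.warn("model selection over a single candidate", stacklevel=2)
    bics = {name: bic(f.objective, f.n_free_parameters, f.n_trials_total)
            for name, f in valid.items()}
    best = min(bics, key=lambda name: (round(bics[name], 12),
                                       valid[name].n_free_parameters,
                                       order.get(name, 99)))
    mn = bics[best]
    return ModelComparison(fits=valid, bics=bics, best=best,
                           delta_bic={n: b - mn for n, b in bics.items()})


def fit_all_models(datasets, config: FitConfig | None = None,
                   refit_on_nesting_violation: bool = True) -> ModelComparison:
    """Fit every candidate scheme to one participant and select by BIC.

    Nesting check: a scheme whose free set contains another's can never
    have a larger optimal objective.  A violation flags optimizer failure
    and triggers one re-fit of the larger scheme started near the smaller
    scheme's solution (via extra restarts with a shifted jitter seed).
    """
    config = config or FitConfig()
    fits = []
    for scheme in build_model_space(len(datasets)):
        try:
            fits.append(fit_participant(datasets, scheme, config))
        except FitFailedError:
            fits.append(None)
    if refit_on_nesting_violation:
        by_name = {f.scheme.name: i for i, f in enumerate(fits) if f is not None}
        for small in SCHEMES:
            for big in SCHEMES:
                if small.name == big.name or small.free >= big.free:
                    continue
                if small.free < big.free and small.name in by_name and big.name in by_name:
                    f_small = fits[by_name[small.name]]
                    f_big = fits[by_name[big.name]]
                    if f_big.objective > f_small.objective + 1e-6:
                        import dataclasses
                        cfg2 = dataclasses.replace(
                            config, jitter_seed=config.jitter_seed + 7919,
                            n_restarts=config.n_restarts + 2)
                        refit = fit_participant(datasets, big, cfg2)
                        if refit.objective < f_big.objective:
                            fits[by_name[big.name]] = refit
    return select_best(fits)


def best_model_counts(comparisons, groups=None) -> pd.DataFrame:
    """Tabulate winning models: schemes as rows, groups as columns.

    ``groups`` is an optional per-participant label sequence; without it a
    single "all" column is produced.  Column sums equal group sizes.
    """
    if len(comparisons) == 0:
        raise ValueError("need at least one participant")
    if groups is None:
        groups = ["all"] * len(comparisons)
    group_levels = list(dict.fromkeys(groups))
    table = pd.DataFrame(0, index=[s.label for s in SCHEMES], columns=group_levels)
    label_of = {s.name: s.label for s in SCHEMES}
    for comp, g in zip(comparisons, groups):
        table.loc[label_of[comp.best], g] += 1
    table.loc["total"] = table.sum(axis=0)
    return table
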