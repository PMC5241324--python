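"""ANT-structured synthetic trial data generated from the DDM.

The Attention Network Task crosses three flanker-congruency conditions
(congruent, neutral, incongruent) with four cue conditions (no cue, center
cue, double cue, time-space cue); a session holds three test blocks of 94
trials presented in random order within each block, after 24 excluded
training trials.

Condition- and group-level diffusion parameters default to the values this
kind of analysis recovers from experienced-meditator cohorts: the decision
threshold is higher for incongruent stimuli (0.27 vs 0.23) and drops with
cue information (0.28 no cue to 0.20 time-space); the drift rate is lower
for incongruent stimuli (0.58 vs 0.79); drift variability is smaller for
incongruent stimuli (0.05 vs 0.07) and larger for time-space cues (0.08 vs
0.06); meditators carry a higher overall threshold than controls (0.25 vs
0.20), with the congruency modulation amplified.  Cell parameters compose
these marginal effects additively; non-decision time is 0.30 s throughout,
the starting point is unbiased (z = a/2) and s = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ddm import DDMParams, SimOptions, simulate_trials

__all__ = [
    "CONGRUENCY_LEVELS",
    "CUE_LEVELS",
    "GROUP_LEVELS",
    "CONGRUENCY_PARAMS",
    "CUE_PARAMS",
    "GROUP_THRESHOLD",
    "ANTDesign",
    "ParticipantSpec",
    "make_ant_design",
    "default_condition_params",
    "generate_participant",
    "generate_cohort",
    "generate_condition_trials",
    "sample_participant_params",
]

CONGRUENCY_LEVELS = ("congruent", "neutral", "incongruent")
CUE_LEVELS = ("no_cue", "center_cue", "double_cue", "time_space_cue")
GROUP_LEVELS = ("meditator", "control")

TER_DEFAULT = 0.30  # s
S_DEFAULT = 0.1

#: marginal (a, v, eta) per congruency condition, collapsed over cues
CONGRUENCY_PARAMS = {
    "congruent": {"a": 0.23, "v": 0.79, "eta": 0.07},
    "neutral": {"a": 0.23, "v": 0.79, "eta": 0.07},
    "incongruent": {"a": 0.27, "v": 0.58, "eta": 0.05},
}

#: marginal (a, v, eta) per cue condition, collapsed over congruency;
#: center/double thresholds interpolate between the no-cue / time-space
#: extremes, and the drift is the congruency grand mean (cue-wise drifts
#: are not separately established)
CUE_PARAMS = {
    "no_cue": {"a": 0.28, "v": 0.72, "eta": 0.06},
    "center_cue": {"a": 0.25, "v": 0.72, "eta": 0.06},
    "double_cue": {"a": 0.24, "v": 0.72, "eta": 0.06},
    "time_space_cue": {"a": 0.20, "v": 0.72, "eta": 0.08},
}

#: group-mean decision thresholds
GROUP_THRESHOLD = {"meditator": 0.25, "control": 0.20}

#: how strongly each group expresses the congruency modulation of the
#: threshold (meditators adapt more); the cohort average stays at 1.0 so
#: combined condition marginals keep their printed differences
GROUP_CONGRUENCY_GAIN = {"meditator": 1.5, "control": 0.5}


@dataclass(frozen=True)
class ANTDesign:
    """Session structure and timing of the ANT."""

    n_blocks: int = 3
    trials_per_block: int = 94
    n_training: int = 24  # excluded from analysis
    cue_levels: tuple = CUE_LEVELS
    congruency_levels: tuple = CONGRUENCY_LEVELS
    fixation_ms: tuple = (400, 1600)  # uniform interval
    cue_ms: int = 100
    cue_target_interval_ms: int = 400
    target_max_ms: int = 1700
    trial_duration_ms: int = 3500

    def __post_init__(self):
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if min(self.cue_ms, self.cue_target_interval_ms, self.target_max_ms,
               self.trial_duration_ms, *self.fixation_ms) <= 0:
            raise ValueError("all timing values must be positive")

    @property
    def n_cells(self):
        return len(self.cue_levels) * len(self.congruency_levels)

    @property
    def n_analyzable(self):
        return self.n_blocks * self.trials_per_block

    def block_allocation(self, block: int) -> dict:
        """Trials per (cue, congruency) cell for one block.

        The trials are spread as evenly as possible over the cells; the
        remainder is taken from cells chosen by rotating through the cell
        list across blocks, so no cell is systematically short.
        """
        cells = [(cu, co) for cu in self.cue_levels for co in self.congruency_levels]
        n_cells = len(cells)
        base, extra = divmod(self.trials_per_block, n_cells)
        alloc = {cell: base for cell in cells}
        if extra:
            # rotate the cells that receive the remainder across blocks
            n_short = n_cells - extra
            start = (block * n_short) % n_cells
            for i in range(extra):
                alloc[cells[(start + n_short + i) % n_cells]] += 1
        return alloc


def make_ant_design(**overrides) -> ANTDesign:
    """The default ANT session design, with field overrides."""
    return ANTDesign(**overrides)


def default_condition_params(group: str, s: float = S_DEFAULT) -> dict:
    """Per-cell DDMParams for one group (12 cells = 4 cues x 3 congruency).

    The threshold composes additively: group mean + group-weighted
    congruency deviation + cue deviation (both deviations centered, so the
    group marginal mean is exact).  Drift and drift variability carry the
    condition effects without a group offset.
    """
    if group not in GROUP_LEVELS:
        raise ValueError(f"unknown group {group!r}")
    a_cong_mean = np.mean([CONGRUENCY_PARAMS[c]["a"] for c in CONGRUENCY_LEVELS])
    a_cue_mean = np.mean([CUE_PARAMS[c]["a"] for c in CUE_LEVELS])
    eta_cue_mean = np.mean([CUE_PARAMS[c]["eta"] for c in CUE_LEVELS])
    gain = GROUP_CONGRUENCY_GAIN[group]
    out = {}
    for cu in CUE_LEVELS:
        for co in CONGRUENCY_LEVELS:
            a = (GROUP_THRESHOLD[group]
                 + gain * (CONGRUENCY_PARAMS[co]["a"] - a_cong_mean)
                 + (CUE_PARAMS[cu]["a"] - a_cue_mean))
            eta = (CONGRUENCY_PARAMS[co]["eta"]
                   + CUE_PARAMS[cu]["eta"] - eta_cue_mean)
            v = CONGRUENCY_PARAMS[co]["v"]
            out[(cu, co)] = DDMParams.symmetric(
                a=a, v=v, ter=TER_DEFAULT, eta=max(eta, 0.0), s=s)
    return out


@dataclass
class ParticipantSpec:
    """One synthetic participant: group, per-cell parameters, seed."""

    participant_id: str
    group: str
    cell_params: dict  # (cue, congruency) -> DDMParams
    contaminant_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.contaminant_rate <= 0.1):
            raise ValueError("contaminant rate must be in [0, 0.1]")


def generate_participant(spec: ParticipantSpec, design: ANTDesign | None = None,
                         session: str = "pre", dt: float = 1e-4) -> pd.DataFrame:
    """Simulate one session of ANT trials for a participant.

    Trials are drawn cell-by-cell from the DDM, shuffled within each
    block, and a fraction ``contaminant_rate`` is replaced by uniform-RT
    guesses on [Ter, 1.7 s] with coin-flip correctness.  Fully
    reproducible from ``spec.rng_seed``.
    """
    design = design or ANTDesign()
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for block in range(design.n_blocks):
        alloc = design.block_allocation(block)
        block_rows = []
        for (cu, co), n in alloc.items():
            if n == 0:
                continue
            p = spec.cell_params[(cu, co)]
            sim = simulate_trials(p, SimOptions(
                n_trials=n, rng_seed=int(rng.integers(2**31 - 1)), dt=dt,
                max_time=design.target_max_ms / 1000.0 + p.ter))
            for j in range(n):
                block_rows.append({
                    "cue_condition": cu, "congruency": co,
                    "correct": int(sim.boundary[j] == 1),
                    "rt": float(sim.rt[j]),
                    "censored": bool(sim.censored[j]),
                })
        rng.shuffle(block_rows)
        for t, row in enumerate(block_rows):
            row["block"] = block + 1
            row["trial"] = t + 1
        rows.extend(block_rows)
    df = pd.DataFrame(rows)
    if spec.contaminant_rate > 0:
        mask = rng.uniform(size=len(df)) < spec.contaminant_rate
        n_cont = int(mask.sum())
        if n_cont:
            ters = np.array([spec.cell_params[(cu, co)].ter
                             for cu, co in zip(df.loc[mask, "cue_condition"],
                                               df.loc[mask, "congruency"])])
            df.loc[mask, "rt"] = rng.uniform(ters, 1.7)
            df.loc[mask, "correct"] = rng.integers(0, 2, n_cont)
            df.loc[mask, "censored"] = False
    df.insert(0, "session", session)
    df.insert(0, "group", spec.group)
    df.insert(0, "participant_id", spec.participant_id)
    return df


def sample_participant_params(group: str, rng: np.random.Generator,
                              cv: float = 0.10, s: float = S_DEFAULT) -> dict:
    """Draw one participant's cell parameters around the group defaults.

    Each of a, v, eta, Ter receives multiplicative normal jitter with
    coefficient of variation ``cv`` (one draw per parameter per
    participant, common to all cells, truncated to the parameter domain).
    """
    base = default_condition_params(group, s=s)
    mult = {name: max(float(rng.normal(1.0, cv)), 0.2)
            for name in ("a", "v", "eta", "ter")}
    out = {}
    for cell, p in base.items():
        out[cell] = DDMParams.symmetric(
            a=p.a * mult["a"], v=p.v * mult["v"], ter=p.ter * mult["ter"],
            eta=p.eta * mult["eta"], s=s)
    return out


def generate_cohort(n_per_group: int, session_structure: str = "single",
                    seed: int = 0, design: ANTDesign | None = None,
                    contaminant_rate: float = 0.0, cv: float = 0.10,
                    dt: float = 1e-4) -> pd.DataFrame:
    """Simulate a meditator + control cohort of full ANT sessions.

    ``session_structure`` is "single" or "pre_post"; pre/post sessions
    share the participant-level parameters (a null retreat effect).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if session_structure not in ("single", "pre_post"):
        raise ValueError("session_structure must be 'single' or 'pre_post'")
    design = design or ANTDesign()
    rng = np.random.default_rng(seed)
    sessions = ("pre",) if session_structure == "single" else ("pre", "post")
    frames = []
    pid = 0
    for group in GROUP_LEVELS:
        for _ in range(n_per_group):
            pid += 1
            spec = ParticipantSpec(
                participant_id=f"p{pid:03d}", group=group,
                cell_params=sample_participant_params(group, rng, cv=cv),
                contaminant_rate=contaminant_rate,
                rng_seed=int(rng.integers(2**31 - 1)))
            for ses in sessions:
                spec_s = replace(spec, rng_seed=int(rng.integers(2**31 - 1)))
                frames.append(generate_participant(spec_s, design, session=ses, dt=dt))
    return pd.concat(frames, ignore_index=True)


def generate_condition_trials(params_by_condition: dict, n_per_condition: int,
                              seed: int = 0, dt: float = 1e-4,
                              max_time: float | None = None):
    """Simulate flat per-condition datasets (no ANT block structure).

    Used for parameter- and model-recovery studies where the trial count
    per condition is inflated well beyond the 94-trial blocks.  Returns a
    list of ``ConditionDataset`` in the order of ``params_by_condition``.
    """
    from .quantile_fit import ConditionDataset

    rng = np.random.default_rng(seed)
    out = []
    for label, p in params_by_condition.items():
        sim = simulate_trials(p, SimOptions(
            n_trials=n_per_condition, rng_seed=int(rng.integers(2**31 - 1)),
            dt=dt, max_time=max_time))
        ok = ~sim.censored
        out.append(ConditionDataset(
            label=label,
            correct_rt=sim.rt[ok & (sim.boundary == 1)],
            error_rt=sim.rt[ok & (sim.boundary == 0)],
            n_censored=int(sim.censored.sum())))
    return out
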