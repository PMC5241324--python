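"""Run configuration: one YAML-serialisable object for the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .quantile_fit import DEFAULT_QUANTILES, FitConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline settings; round-trips losslessly through YAML."""

    seed: int = 0
    quantile_probs: tuple = DEFAULT_QUANTILES
    trim_threshold: float = 0.150
    objective: str = "multinomial"
    n_restarts: int = 5
    maxiter: int = 2000
    estimate_sz_st: bool = False
    n_per_group: int = 20
    session_structure: str = "single"
    contaminant_rate: float = 0.0
    between_participant_cv: float = 0.10
    sim_dt: float = 1e-4

    def __post_init__(self):
        self.quantile_probs = tuple(float(q) for q in self.quantile_probs)
        if not all(0.0 < q < 1.0 for q in self.quantile_probs):
            raise ValueError("quantile probs must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.quantile_probs, self.quantile_probs[1:])):
            raise ValueError("quantile probs must be strictly increasing")
        if self.objective not in ("multinomial", "pearson"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.session_structure not in ("single", "pre_post"):
            raise ValueError("session_structure must be 'single' or 'pre_post'")
        if not (0.0 <= self.contaminant_rate <= 0.1):
            raise ValueError("contaminant_rate must be in [0, 0.1]")
        if self.n_restarts < 1 or self.maxiter < 1 or self.n_per_group < 1:
            raise ValueError("counts must be positive")

    def fit_config(self, jitter_seed: int | None = None) -> FitConfig:
        return FitConfig(
            quantile_probs=self.quantile_probs,
            trim_threshold=self.trim_threshold,
            objective=self.objective,
            n_restarts=self.n_restarts,
            maxiter=self.maxiter,
            estimate_sz_st=self.estimate_sz_st,
            jitter_seed=self.seed if jitter_seed is None else jitter_seed)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["quantile_probs"] = list(self.quantile_probs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
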