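"""Full drift diffusion model: distributions, bin probabilities, simulator.

The model describes two-choice decisions as a Wiener process with drift
``v`` and diffusion coefficient ``s`` started at ``z`` between absorbing
boundaries 0 and ``a``.  Crossing the upper boundary produces the correct
response (accuracy coding), the lower boundary an error; the response time
is the boundary-crossing time plus a non-decision time ``Ter``.  Across
trials the drift is Normal(v, eta), the starting point Uniform(z-sz, z+sz)
and the non-decision time Uniform(Ter-st, Ter+st).

The scaling constant ``s`` defaults to 0.1, the convention in which
thresholds of ~0.2 and drifts of ~0.6-0.8 are typical for fast perceptual
decisions.  Multiplying a, z, v, eta, sz and s by a common factor leaves
every prediction unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _fpt
from ._simulate import simulate_kernel

__all__ = [
    "DDMParams",
    "SimOptions",
    "SimResult",
    "ParameterError",
    "choice_probability",
    "first_passage_density",
    "first_passage_cdf",
    "mean_decision_time",
    "predicted_bin_probabilities",
    "simulate_trials",
]

#: variability parameters below this are treated as exactly zero
ZERO_TOL = 1e-10

# quadrature rules shared by all variability integrals
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(24)
_GL_X, _GL_W = np.polynomial.legendre.leggauss(12)


class ParameterError(ValueError):
    """Raised when diffusion parameters violate their domain."""


@dataclass(frozen=True)
class DDMParams:
    """One condition's diffusion parameters.

    a : decision threshold (boundary separation, evidence units)
    v : mean drift rate (evidence units / s), positive toward correct
    z : starting point, 0 < z < a
    ter : non-decision time (s)
    eta : across-trial SD of the drift rate
    sz : half-range of uniform starting-point variability
    st : half-range of uniform non-decision-time variability
    s : within-trial diffusion coefficient (scaling constant)
    """

    a: float
    v: float
    z: float
    ter: float
    eta: float = 0.0
    sz: float = 0.0
    st: float = 0.0
    s: float = 0.1

    def __post_init__(self):
        if not (self.a > 0.0):
            raise ParameterError(f"threshold a must be positive, got {self.a}")
        if not (0.0 < self.z < self.a):
            raise ParameterError(f"starting point z={self.z} outside (0, a={self.a})")
        if self.eta < 0.0 or self.sz < 0.0 or self.st < 0.0:
            raise ParameterError("variability parameters must be nonnegative")
        if self.sz > 0.0 and not (self.z - self.sz > 0.0 and self.z + self.sz < self.a):
            raise ParameterError("starting-point range [z-sz, z+sz] must lie inside (0, a)")
        if self.ter - self.st < 0.0:
            raise ParameterError("non-decision time range must be nonnegative")
        if not (self.s > 0.0):
            raise ParameterError("diffusion coefficient s must be positive")

    @classmethod
    def symmetric(cls, a, v, ter, eta=0.0, sz=0.0, st=0.0, s=0.1):
        """Parameters with an unbiased starting point z = a/2."""
        return cls(a=a, v=v, z=a / 2.0, ter=ter, eta=eta, sz=sz, st=st, s=s)

    def _normalized(self):
        """(v', a', z', eta', sz') in unit-diffusion coordinates."""
        eta = self.eta if self.eta > ZERO_TOL else 0.0
        sz = self.sz if self.sz > ZERO_TOL else 0.0
        return (self.v / self.s, self.a / self.s, self.z / self.s,
                eta / self.s, sz / self.s)

    def _st(self):
        return self.st if self.st > ZERO_TOL else 0.0


@dataclass(frozen=True)
class SimOptions:
    """Simulator settings: Euler step, trial count, seed, censoring horizon."""

    n_trials: int
    rng_seed: int
    dt: float = 1e-4
    max_time: float | None = None  # default: 1.7 s target window + Ter

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (self.dt > 0.0):
            raise ValueError("dt must be positive")


@dataclass
class SimResult:
    rt: np.ndarray        # response times, seconds
    boundary: np.ndarray  # 1 upper (correct), 0 lower (error), -1 censored
    censored: np.ndarray  # bool

    def __len__(self):
        return len(self.rt)


def _check_boundary(boundary):
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary == "upper"


def choice_probability(params: DDMParams, boundary: str = "upper") -> float:
    """Probability of absorption at the named boundary."""
    upper = _check_boundary(boundary)
    v, a, z, eta, sz = params._normalized()
    return float(_fpt.choice_prob_var(v, a, z, eta, sz, upper,
                                      _GH_X, _GH_W, _GL_X, _GL_W))


def first_passage_density(params: DDMParams, t, boundary: str = "upper"):
    """Defective density of the response time (decision + non-decision)."""
    upper = _check_boundary(boundary)
    v, a, z, eta, sz = params._normalized()
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = _fpt.dens_var(ts, v, a, z, eta, sz, params.ter, params._st(),
                        upper, _GH_X, _GH_W, _GL_X, _GL_W)
    return float(out[0]) if np.isscalar(t) else out


def first_passage_cdf(params: DDMParams, t, boundary: str = "upper"):
    """P(RT <= t, response at the named boundary); tends to the choice probability."""
    upper = _check_boundary(boundary)
    v, a, z, eta, sz = params._normalized()
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = _fpt.cdf_var(ts, v, a, z, eta, sz, params.ter, params._st(),
                       upper, _GH_X, _GH_W, _GL_X, _GL_W)
    return float(out[0]) if np.isscalar(t) else out


def mean_decision_time(params: DDMParams) -> float:
    """Expected decision time (excluding Ter), both boundaries combined.

    Conditional on the trial's drift u and start y the mean exit time has
    the closed form (a P_upper(u, y) - y)/u (limit y(a-y)/s^2 at u = 0);
    drift and starting-point variability are integrated by quadrature.
    """
    v, a, z, eta, sz = params._normalized()

    def _m(u, y):
        if abs(u) < 1e-9:
            return y * (a - y)
        return (a * _fpt.p_lower(-u, a, a - y) - y) / u

    vs = [v] if eta == 0.0 else [v + math.sqrt(2.0) * eta * x for x in _GH_X]
    wv = [1.0] if eta == 0.0 else list(_GH_W)
    zs = [z] if sz == 0.0 else [z + sz * x for x in _GL_X]
    wz = [1.0] if sz == 0.0 else [0.5 * w for w in _GL_W]
    acc = sum(wi * wj * _m(u, y) for u, wi in zip(vs, wv) for y, wj in zip(zs, wz))
    return float(acc / (sum(wv) * sum(wz)))


def predicted_bin_probabilities(params: DDMParams, correct_edges,
                                error_edges=None):
    """Model probability mass between empirical quantile edges.

    ``correct_edges`` / ``error_edges`` are strictly increasing RT edges in
    seconds (an empty/None side collapses to a single bin holding that
    response's full probability).  Returns ``(correct_masses,
    error_masses)``; all masses sum to 1.
    """
    ce = np.asarray([] if correct_edges is None else correct_edges, dtype=float)
    ee = np.asarray([] if error_edges is None else error_edges, dtype=float)
    for edges in (ce, ee):
        if edges.size > 1 and not np.all(np.diff(edges) > 0.0):
            raise ValueError("quantile edges must be strictly increasing")
    v, a, z, eta, sz = params._normalized()
    pc, pe = _fpt.bin_probs(ce, ee, v, a, z, eta, sz, params.ter, params._st(),
                            _GH_X, _GH_W, _GL_X, _GL_W)
    return pc, pe


def simulate_trials(params: DDMParams, opts: SimOptions) -> SimResult:
    """Euler-Maruyama simulation of full-DDM trials.

    Per trial the drift is Normal(v, eta), the start Uniform(z-sz, z+sz)
    and the non-decision time Uniform(Ter-st, Ter+st); RT = decision time
    + non-decision draw.  Trials undecided at ``max_time`` are censored.
    Reproducible given ``rng_seed``.
    """
    max_time = opts.max_time if opts.max_time is not None else 1.7 + params.ter
    if max_time <= params.ter:
        raise ValueError("max_time must exceed Ter")
    if params.s * math.sqrt(opts.dt) > 0.1 * min(params.z, params.a - params.z):
        warnings.warn(
            "Euler step dt is coarse relative to the boundary separation; "
            "discretization bias may be noticeable", stacklevel=2)
    rt, boundary, censored = simulate_kernel(
        opts.n_trials, params.a, params.v, params.z, params.ter,
        params.eta if params.eta > ZERO_TOL else 0.0,
        params.sz if params.sz > ZERO_TOL else 0.0,
        params.st if params.st > ZERO_TOL else 0.0,
        params.s, opts.dt, max_time, opts.rng_seed)
    return SimResult(rt=rt, boundary=boundary, censored=censored.astype(bool))
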