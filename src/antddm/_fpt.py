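"""Low-level first-passage-time kernels for the two-boundary Wiener process.

Everything here works in unit-diffusion coordinates: a process with drift
``v``, diffusion coefficient 1, started at ``z`` between absorbing
boundaries 0 and ``a``.  Callers normalise physical parameters by the
diffusion coefficient ``s`` (a' = a/s, v' = v/s, ...), which leaves all
first-passage distributions unchanged.

Two classical series expansions of the defective first-passage density at
the lower boundary are implemented: the method-of-images ("small-time")
form and the spectral ("large-time") form.  Each routine picks the series
that needs fewer terms, with a stability guard on the spectral prefactor
exp(-v z): when the drift pushes strongly toward the boundary under
consideration the spectral terms become huge and cancel, so the image
series (whose per-term exponents are combined before exponentiation and
are always <= 0) is used instead.

All routines are numba-compiled; upper-boundary quantities use the exact
reflection v -> -v, z -> a - z.
"""

import numpy as np
from numba import njit

# ln(eps) used for series truncation; eps ~ 1e-20 absolute.
_LOG_EPS = 46.0
# Largest spectral-series exponent we accept before cancellation bites.
_MAX_EXP = 28.0


@njit(cache=True)
def p_lower(v, a, z):
    """Absorption probability at the lower boundary (unit diffusion)."""
    if abs(v) < 1e-12:
        return 1.0 - z / a
    if v > 0.0:
        # (e^{-2vz} - e^{-2va}) / (1 - e^{-2va}); exponents <= 0
        return (np.exp(-2.0 * v * z) - np.exp(-2.0 * v * a)) / (
            -np.expm1(-2.0 * v * a)
        )
    # v < 0: multiply through by e^{2va} so all exponents stay <= 0
    return np.expm1(2.0 * v * (a - z)) / np.expm1(2.0 * v * a)


@njit(cache=True)
def _dens_small(t, v, a, z):
    """Method-of-images series for the lower-boundary density."""
    n_img = int(np.ceil((np.sqrt(2.0 * t * _LOG_EPS) + z) / (2.0 * a))) + 1
    base = -v * z - 0.5 * v * v * t
    acc = 0.0
    for k in range(-n_img, n_img + 1):
        w = z + 2.0 * k * a
        e = base - w * w / (2.0 * t)
        if e > -700.0:
            acc += w * np.exp(e)
    if acc < 0.0:
        acc = 0.0
    return acc / np.sqrt(2.0 * np.pi * t * t * t)


@njit(cache=True)
def _dens_large(t, v, a, z):
    """Spectral series for the lower-boundary density."""
    n_terms = int(np.ceil((a / np.pi) * np.sqrt(2.0 * _LOG_EPS / t))) + 1
    base = -v * z - 0.5 * v * v * t
    c = np.pi * np.pi / (2.0 * a * a)
    acc = 0.0
    for k in range(1, n_terms + 1):
        acc += k * np.sin(k * np.pi * z / a) * np.exp(base - c * k * k * t)
    if acc < 0.0:
        acc = 0.0
    return acc * np.pi / (a * a)


@njit(cache=True)
def dens_lower(t, v, a, z):
    """Defective density of the decision time at the lower boundary."""
    if t <= 0.0:
        return 0.0
    base = -v * z - 0.5 * v * v * t
    k_large = (a / np.pi) * np.sqrt(2.0 * _LOG_EPS / t)
    k_small = (np.sqrt(2.0 * t * _LOG_EPS) + z) / (2.0 * a)
    if base > _MAX_EXP or k_small < k_large:
        return _dens_small(t, v, a, z)
    return _dens_large(t, v, a, z)


# 16-point Gauss-Legendre rule on [-1, 1], used by the quadrature fallback.
_GL16_X, _GL16_W = np.polynomial.legendre.leggauss(16)


@njit(cache=True)
def cdf_lower(t, v, a, z):
    """P(decision time <= t, absorbed at lower boundary)."""
    if t <= 0.0:
        return 0.0
    pl = p_lower(v, a, z)
    if pl <= 0.0:
        return 0.0
    c = np.pi * np.pi / (2.0 * a * a)
    top_exp = -v * z - (0.5 * v * v + c) * t
    k_large = (a / np.pi) * np.sqrt(2.0 * _LOG_EPS / t)
    if top_exp <= _MAX_EXP and k_large <= 400.0:
        n_terms = int(np.ceil(k_large)) + 1
        acc = 0.0
        for k in range(1, n_terms + 1):
            lam = 0.5 * v * v + c * k * k
            acc += (k / lam) * np.sin(k * np.pi * z / a) * np.exp(
                -v * z - lam * t
            )
        f = pl - acc * np.pi / (a * a)
    else:
        # composite Gauss-Legendre quadrature of the image-series density;
        # only reached for very small t or extreme drift toward the boundary
        acc = 0.0
        n_pan = 8
        for p in range(n_pan):
            lo = t * p / n_pan
            hi = t * (p + 1) / n_pan
            half = 0.5 * (hi - lo)
            mid = 0.5 * (hi + lo)
            for i in range(_GL16_X.shape[0]):
                acc += half * _GL16_W[i] * _dens_small(
                    mid + half * _GL16_X[i], v, a, z
                )
        f = acc
    if f < 0.0:
        f = 0.0
    if f > pl:
        f = pl
    return f


@njit(cache=True)
def dens_boundary(t, v, a, z, upper):
    if upper:
        return dens_lower(t, -v, a, a - z)
    return dens_lower(t, v, a, z)


@njit(cache=True)
def cdf_boundary(t, v, a, z, upper):
    if upper:
        return cdf_lower(t, -v, a, a - z)
    return cdf_lower(t, v, a, z)


@njit(cache=True)
def p_boundary(v, a, z, upper):
    if upper:
        return p_lower(-v, a, a - z)
    return p_lower(v, a, z)


# ---------------------------------------------------------------------------
# Across-trial variability: normal drift (Gauss-Hermite), uniform starting
# point and uniform non-decision time (Gauss-Legendre).
# ---------------------------------------------------------------------------

@njit(cache=True)
def choice_prob_var(v0, a, z, eta, sz, upper, ghx, ghw, glx, glw):
    """Choice probability integrated over drift and starting-point variability."""
    n_gh = ghx.shape[0] if eta > 0.0 else 1
    n_gl = glx.shape[0] if sz > 0.0 else 1
    acc = 0.0
    wtot = 0.0
    for i in range(n_gh):
        if eta > 0.0:
            vi = v0 + np.sqrt(2.0) * eta * ghx[i]
            wi = ghw[i]
        else:
            vi = v0
            wi = 1.0
        for j in range(n_gl):
            if sz > 0.0:
                zj = z + sz * glx[j]
                wj = 0.5 * glw[j]
            else:
                zj = z
                wj = 1.0
            acc += wi * wj * p_boundary(vi, a, zj, upper)
            wtot += wi * wj
    return acc / wtot


@njit(cache=True)
def cdf_var(ts, v0, a, z, eta, sz, ter, st, upper, ghx, ghw, glx, glw):
    """First-passage CDF of the *response time* at one boundary.

    ``ts`` are RTs in seconds; the decision-time CDF is evaluated at
    t - ter, integrated over drift (eta), starting point (sz) and
    non-decision time (st) variability.  Parameters v0, a, z, eta, sz are
    in unit-diffusion coordinates; ter/st in seconds.
    """
    out = np.zeros(ts.shape[0])
    n_gh = ghx.shape[0] if eta > 0.0 else 1
    n_gz = glx.shape[0] if sz > 0.0 else 1
    n_gt = glx.shape[0] if st > 0.0 else 1
    wtot = 0.0
    for i in range(n_gh):
        if eta > 0.0:
            vi = v0 + np.sqrt(2.0) * eta * ghx[i]
            wi = ghw[i]
        else:
            vi = v0
            wi = 1.0
        for j in range(n_gz):
            if sz > 0.0:
                zj = z + sz * glx[j]
                wj = 0.5 * glw[j]
            else:
                zj = z
                wj = 1.0
            for m in range(n_gt):
                if st > 0.0:
                    tm = ter + st * glx[m]
                    wm = 0.5 * glw[m]
                else:
                    tm = ter
                    wm = 1.0
                w = wi * wj * wm
                wtot += w
                for q in range(ts.shape[0]):
                    td = ts[q] - tm
                    if td > 0.0:
                        out[q] += w * cdf_boundary(td, vi, a, zj, upper)
    return out / wtot


@njit(cache=True)
def dens_var(ts, v0, a, z, eta, sz, ter, st, upper, ghx, ghw, glx, glw):
    """Defective RT density at one boundary with across-trial variability."""
    out = np.zeros(ts.shape[0])
    n_gh = ghx.shape[0] if eta > 0.0 else 1
    n_gz = glx.shape[0] if sz > 0.0 else 1
    n_gt = glx.shape[0] if st > 0.0 else 1
    wtot = 0.0
    for i in range(n_gh):
        if eta > 0.0:
            vi = v0 + np.sqrt(2.0) * eta * ghx[i]
            wi = ghw[i]
        else:
            vi = v0
            wi = 1.0
        for j in range(n_gz):
            if sz > 0.0:
                zj = z + sz * glx[j]
                wj = 0.5 * glw[j]
            else:
                zj = z
                wj = 1.0
            for m in range(n_gt):
                if st > 0.0:
                    tm = ter + st * glx[m]
                    wm = 0.5 * glw[m]
                else:
                    tm = ter
                    wm = 1.0
                w = wi * wj * wm
                wtot += w
                for q in range(ts.shape[0]):
                    td = ts[q] - tm
                    if td > 0.0:
                        out[q] += w * dens_boundary(td, vi, a, zj, upper)
    return out / wtot


@njit(cache=True)
def bin_probs(correct_edges, error_edges, v, a, z, eta, sz, ter, st,
              ghx, ghw, glx, glw):
    """Model probability mass in quantile bins for one condition.

    Edges are RTs in seconds (possibly empty arrays, meaning the side is a
    single collapsed bin).  Returns (correct_masses, error_masses); all
    masses together sum to 1.  Parameters are unit-diffusion normalised
    except ter/st.
    """
    pu = choice_prob_var(v, a, z, eta, sz, True, ghx, ghw, glx, glw)
    pl = 1.0 - pu
    nc = correct_edges.shape[0]
    ne = error_edges.shape[0]
    pc = np.empty(nc + 1)
    pe = np.empty(ne + 1)
    if nc > 0:
        fc = cdf_var(correct_edges, v, a, z, eta, sz, ter, st, True,
                     ghx, ghw, glx, glw)
        prev = 0.0
        for i in range(nc):
            pc[i] = max(fc[i] - prev, 0.0)
            prev = fc[i]
        pc[nc] = max(pu - prev, 0.0)
    else:
        pc[0] = pu
    if ne > 0:
        fe = cdf_var(error_edges, v, a, z, eta, sz, ter, st, False,
                     ghx, ghw, glx, glw)
        prev = 0.0
        for i in range(ne):
            pe[i] = max(fe[i] - prev, 0.0)
            prev = fe[i]
        pe[ne] = max(pl - prev, 0.0)
    else:
        pe[0] = pl
    return pc, pe
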