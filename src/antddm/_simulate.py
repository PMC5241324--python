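"""Euler-Maruyama trial simulator (numba kernel)."""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_kernel(n, a, v, z, ter, eta, sz, st, s, dt, max_time, seed):
    """Simulate ``n`` diffusion trials.

    Returns (rt, boundary, censored): boundary is 1 for upper, 0 for lower,
    -1 for trials still undecided at the censoring horizon (their rt is set
    to ``max_time``).
    """
    np.random.seed(seed)
    rt = np.empty(n)
    boundary = np.empty(n, dtype=np.int8)
    censored = np.zeros(n, dtype=np.int8)
    sq = s * np.sqrt(dt)
    for i in range(n):
        vi = v
        if eta > 0.0:
            vi = v + eta * np.random.randn()
        zi = z
        if sz > 0.0:
            zi = z + np.random.uniform(-sz, sz)
        ti = ter
        if st > 0.0:
            ti = ter + np.random.uniform(-st, st)
        x = zi
        t = 0.0
        t_limit = max_time - ti
        step_var = sq * sq  # s^2 dt
        while True:
            x_prev = x
            x += vi * dt + sq * np.random.randn()
            t += dt
            if x >= a:
                boundary[i] = 1
                break
            if x <= 0.0:
                boundary[i] = 0
                break
            # Brownian-bridge test for an unobserved within-step crossing;
            # removes the discrete-monitoring bias of plain Euler steps
            p_up = np.exp(-2.0 * (a - x_prev) * (a - x) / step_var)
            p_lo = np.exp(-2.0 * x_prev * x / step_var)
            if p_up + p_lo > 1e-14:
                u = np.random.random()
                if u < p_up:
                    boundary[i] = 1
                    break
                if u > 1.0 - p_lo:
                    boundary[i] = 0
                    break
            if t >= t_limit:
                boundary[i] = -1
                censored[i] = 1
                break
        if censored[i] == 1:
            rt[i] = max_time
        else:
            rt[i] = t + ti
    return rt, boundary, censored
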