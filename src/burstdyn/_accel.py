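"""Numba kernels for the sequential stochastic integrators.

Euler-Maruyama recursions are inherently serial; these kernels keep the
polynomial envelope model, the tabulated-drift simulator, and the delayed
Wilson-Cowan model fast enough for long synthetic recordings.
"""

import numba
import numpy as np

__all__ = ["euler_poly", "euler_interp_drift", "wc_loop"]


@numba.njit(cache=True)
def euler_poly(coeffs, zeta, dt, n_steps, x0, noise):
    """x <- |x + mu(x) dt + zeta sqrt(dt) n|, polynomial mu (ascending coeffs).

    Returns the trajectory including x0 at index 0; raises on divergence
    (|x| > 1e6) via a sentinel: the first output value is set to NaN.
    """
    out = np.empty(n_steps + 1)
    out[0] = x0
    sq = zeta * np.sqrt(dt)
    x = x0
    deg = len(coeffs) - 1
    for i in range(n_steps):
        mu = coeffs[deg]
        for k in range(deg - 1, -1, -1):
            mu = mu * x + coeffs[k]
        x = abs(x + mu * dt + sq * noise[i])
        if x > 1e6:
            out[0] = np.nan
            return out
        out[i + 1] = x
    return out


@numba.njit(cache=True)
def euler_interp_drift(x_grid, mu_grid, zeta, dt, n_steps, x0, noise):
    """Euler-Maruyama with clamped linear interpolation of a tabulated drift.

    Queries below x_grid[0] use mu_grid[0]; above x_grid[-1], mu_grid[-1].
    Positivity is enforced by retaining the absolute value of each step.
    """
    out = np.empty(n_steps + 1)
    out[0] = x0
    sq = zeta * np.sqrt(dt)
    x = x0
    n = len(x_grid)
    inv_dx = (n - 1) / (x_grid[-1] - x_grid[0])
    for i in range(n_steps):
        if x <= x_grid[0]:
            mu = mu_grid[0]
        elif x >= x_grid[-1]:
            mu = mu_grid[-1]
        else:
            j = int((x - x_grid[0]) * inv_dx)
            if j >= n - 1:
                j = n - 2
            w = (x - x_grid[j]) / (x_grid[j + 1] - x_grid[j])
            mu = mu_grid[j] * (1.0 - w) + mu_grid[j + 1] * w
        x = abs(x + mu * dt + sq * noise[i])
        if x > 1e6:
            out[0] = np.nan
            return out
        out[i + 1] = x
    return out


@numba.njit(cache=True)
def wc_loop(dt, n_steps, omega_e, omega_i, w_ie, w_ei, w_ii,
            lam_e, lam_i, zeta, sigmoid, beta, eta,
            d_ie, d_ei, d_ii, noise_e, noise_i, e0, i0):
    """Two-population stochastic Wilson-Cowan integration with delays.

    ``d_pr`` are delays in integer steps (from population P to R). History
    before t=0 is held constant at the initial state. ``sigmoid`` selects
    g(x) = eta / (1 + exp(-beta (x - 1))); otherwise f(x) = beta * x.
    Returns (E, I) including the initial state; E[0] is NaN on divergence.
    """
    E = np.empty(n_steps + 1)
    I = np.empty(n_steps + 1)
    E[0] = e0
    I[0] = i0
    sq = zeta * np.sqrt(dt)
    for t in range(n_steps):
        ti_ie = t - d_ie if t >= d_ie else 0    # I state entering dE
        te_ei = t - d_ei if t >= d_ei else 0    # E state entering dI
        ti_ii = t - d_ii if t >= d_ii else 0    # I state entering dI
        in_e = lam_e - w_ie * I[ti_ie]
        in_i = -lam_i + w_ei * E[te_ei] - w_ii * I[ti_ii]
        if sigmoid:
            act_e = eta / (1.0 + np.exp(-beta * (in_e - 1.0)))
            act_i = eta / (1.0 + np.exp(-beta * (in_i - 1.0)))
        else:
            act_e = beta * in_e
            act_i = beta * in_i
        e_new = E[t] + dt / omega_e * (-E[t] + act_e) + sq * noise_e[t]
        i_new = I[t] + dt / omega_i * (-I[t] + act_i) + sq * noise_i[t]
        if abs(e_new) > 1e6 or abs(i_new) > 1e6:
            E[0] = np.nan
            return E, I
        E[t + 1] = e_new
        I[t + 1] = i_new
    return E, I
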