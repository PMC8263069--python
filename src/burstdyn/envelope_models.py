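"""Stochastic envelope models: Ornstein-Uhlenbeck and polynomial drift.

An envelope model is a one-dimensional SDE ``dx = mu(x) dt + zeta dW`` whose
time discretization directly models the amplitude envelope of a band-limited
oscillation. Linear drift ``mu = -theta x`` (OU) captures most simple burst
duration profiles; polynomial drift of higher degree adds the non-linear
structure seen in more complex profiles. Oscillatory activity is synthesized
by modulating a constant-frequency carrier with the envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ._accel import euler_poly
from .types import Envelope, TimeSeries

__all__ = [
    "PolynomialDrift",
    "ou_drift",
    "ou_exact_path",
    "rayleigh_drift_duration",
    "simulate_ou",
    "simulate_polynomial",
    "synthesize_oscillation",
]

DEFAULT_DT = 1e-3  # seconds; integration step, roughly the data sampling rate
BURN_IN = 10.0  # seconds discarded before analysis


@dataclass(frozen=True)
class PolynomialDrift:
    """Polynomial drift mu(x) = sum_i d_i x^i with d_degree < 0.

    A negative leading coefficient makes the stationary density (which is
    proportional to exp(2*Lambda(x)/zeta^2)) integrable.
    """

    coeffs: np.ndarray  # ascending d_0 .. d_{n_P}

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if len(c) < 2:
            raise ValueError("drift needs degree >= 1")
        if c[-1] >= 0:
            raise ValueError("leading coefficient must be negative")
        object.__setattr__(self, "coeffs", c)

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coeffs)

    def antiderivative(self, x):
        """Lambda(x) = sum_i d_i x^{i+1}/(i+1), with Lambda(0) = 0."""
        lam = np.concatenate(([0.0], self.coeffs / np.arange(1, len(self.coeffs) + 1)))
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), lam)

    def stable_roots(self) -> np.ndarray:
        """Real roots of mu with mu' < 0 (attracting fixed points)."""
        roots = np.polynomial.polynomial.polyroots(self.coeffs)
        real = roots[np.abs(roots.imag) < 1e-9].real
        deriv = np.polynomial.polynomial.polyder(self.coeffs)
        slope = np.polynomial.polynomial.polyval(real, deriv)
        return np.sort(real[slope < 0])


def ou_drift(theta: float) -> PolynomialDrift:
    """Linear drift mu(x) = -theta * x."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return PolynomialDrift(np.array([0.0, -theta]))


def ou_exact_path(theta: float, zeta: float, dt: float, n: int,
                  seed: int = 0) -> np.ndarray:
    """Raw (unshifted, possibly negative) exact-updating OU trajectory.

    Started from a stationary draw; the linear recursion is evaluated as an
    IIR filter of the noise stream.
    """
    if theta <= 0 or zeta <= 0:
        raise ValueError("theta and zeta must be positive")
    rng = np.random.default_rng(seed)
    a = math.exp(-theta * dt)
    s = math.sqrt(zeta**2 * (1.0 - a * a) / (2.0 * theta))
    x0 = rng.normal(0.0, zeta / math.sqrt(2.0 * theta))
    noise = rng.standard_normal(n)
    return lfilter([s], [1.0, -a], noise, zi=np.array([a * x0]))[0]


def simulate_ou(theta: float, zeta: float, dt: float, duration: float,
                seed: int = 0, shift: bool = True,
                burn_in: float = BURN_IN) -> Envelope:
    """Simulate a discretized OU process with the exact updating equation.

    x(t+dt) = x(t) e^{-theta dt} + n * sqrt(zeta^2 (1 - e^{-2 theta dt}) / (2 theta))

    started from the stationary law. Positivity: the trajectory is shifted
    upward by the absolute value of its 0.1th percentile and floored at 0.
    The shift is percentile-threshold neutral, so burst duration profiles
    (thresholds as percentiles) are unaffected.
    """
    n_total = int(round((duration + burn_in) / dt))
    x = ou_exact_path(theta, zeta, dt, n_total, seed=seed)
    x = x[int(round(burn_in / dt)):]
    if shift:
        x = x + abs(np.percentile(x, 0.1))
        np.clip(x, 0.0, None, out=x)
    else:
        # positivity for the Envelope container without altering percentile
        # ranks: shift by the sample minimum instead
        x = x - x.min()
    return Envelope(x, dt)


def simulate_polynomial(drift: PolynomialDrift, zeta: float, dt: float,
                        duration: float, seed: int = 0, x0: float | None = None,
                        burn_in: float = BURN_IN) -> Envelope:
    """Euler-Maruyama simulation of a polynomial-drift envelope model.

    Positivity is enforced by retaining the absolute value of each new point
    (a reflection at 0, negligible for thresholds well above 0). The initial
    state defaults to the largest attracting root of the drift (or 0 when
    none exists on the positive axis); a 10 s burn-in is discarded.
    """
    if not isinstance(drift, PolynomialDrift):
        drift = PolynomialDrift(np.asarray(drift, dtype=float))
    if zeta < 0:
        raise ValueError("zeta must be non-negative (0 = deterministic flow)")
    if x0 is None:
        roots = drift.stable_roots()
        x0 = float(roots[-1]) if len(roots) else 0.0
    rng = np.random.default_rng(seed)
    n_total = int(round((duration + burn_in) / dt))
    noise = rng.standard_normal(n_total)
    traj = euler_poly(drift.coeffs, zeta, dt, n_total, float(x0), noise)
    if np.isnan(traj[0]):
        raise FloatingPointError(
            f"trajectory diverged (|x| > 1e6); drift={drift.coeffs.tolist()}, "
            f"zeta={zeta}, dt={dt}")
    return Envelope(traj[int(round(burn_in / dt)) + 1:], dt)


def synthesize_oscillation(env: Envelope, nu: float,
                           target_sd: float | None = None) -> TimeSeries:
    """Modulate a constant-frequency carrier with an envelope.

    z(t) = x(t) cos(2 pi nu t). With ``target_sd`` the output is rescaled so
    its standard deviation matches the target (used when matching a model to
    z-scored data).
    """
    if nu >= 0.5 / env.dt:
        raise ValueError("carrier frequency must be below Nyquist")
    t = np.arange(len(env)) * env.dt
    z = env.values * np.cos(2.0 * math.pi * nu * t)
    if target_sd is not None:
        sd = z.std()
        if sd > 0:
            z = z * (target_sd / sd)
    return TimeSeries(z, env.dt)


def rayleigh_drift_duration(theta: float, zeta: float):
    """Callable Rayleigh drift mu(x) = -theta x + zeta^2/(2x) (x > 0)."""
    def mu(x):
        x = np.asarray(x, dtype=float)
        return -theta * x + zeta**2 / (2.0 * x)
    return mu


def stationary_density_grid(drift: PolynomialDrift, zeta: float,
                            n_points: int = 2000):
    """Stationary density of the reflected positive-envelope model.

    With a reflecting boundary at 0 the zero-flux stationary density is
    p(x) proportional to exp(2*Lambda(x)/zeta^2) on [0, inf). Returns
    (x_grid, normalized density) truncated where the density falls below
    1e-14 of its maximum.
    """
    # locate a generous upper bound by expanding until the log-density drops
    x_hi = 1.0
    lam0 = drift.antiderivative(np.linspace(0, x_hi, 256))
    ref = lam0.max()
    for _ in range(60):
        if 2.0 * (drift.antiderivative(x_hi) - ref) / zeta**2 < -40.0:
            break
        x_hi *= 1.5
    x = np.linspace(0.0, x_hi, n_points)
    log_p = 2.0 * drift.antiderivative(x) / zeta**2
    log_p -= log_p.max()
    p = np.exp(log_p)
    z = np.trapezoid(p, x)
    return x, p / z
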