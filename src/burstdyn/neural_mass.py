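"""Stochastic Wilson-Cowan model of the STN-GPe loop.

An excitatory population E (subthalamic nucleus; its activity stands in for
the recorded LFP) and an inhibitory population I (external globus pallidus)
interact through weights w_EI, w_IE and the self-inhibition w_II, driven by
constant inputs and independent Gaussian white noise. The activation is
either linear, f(x) = beta*x (with zero delays), or a delayed sigmoid
g(x) = eta / (1 + exp(-beta*(x - 1))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._accel import wc_loop
from .features import burst_profiles, hilbert_envelope, psd
from .types import Envelope, SpectralDensity, ThresholdProfile, TimeSeries, DEFAULT_PERCENTILES

__all__ = ["WCParameters", "simulate_wc", "wc_features", "linear_drift_matrix",
           "linear_peak_frequency"]


@dataclass(frozen=True)
class WCParameters:
    """Parameters of the two-population stochastic Wilson-Cowan model.

    Weights are non-negative; time constants are in seconds; delays (seconds)
    apply per connection and are rounded to integer multiples of the
    integration step. ``activation`` is "linear" or "sigmoid".
    """

    w_ie: float
    w_ei: float
    w_ii: float
    lambda_e: float = 0.0
    lambda_i: float = 0.0
    omega_e: float = 0.01
    omega_i: float = 0.01
    zeta: float = 1.0
    activation: str = "linear"
    beta: float = 1.0
    eta: float = 1.0
    delta_ei: float = 0.0
    delta_ie: float = 0.0
    delta_ii: float = 0.0

    def __post_init__(self):
        if min(self.w_ie, self.w_ei, self.w_ii) < 0:
            raise ValueError("weights must be non-negative")
        if self.omega_e <= 0 or self.omega_i <= 0:
            raise ValueError("time constants must be positive")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative (0 = deterministic)")
        if min(self.delta_ei, self.delta_ie, self.delta_ii) < 0:
            raise ValueError("delays must be non-negative")
        if self.activation not in ("linear", "sigmoid"):
            raise ValueError("activation must be 'linear' or 'sigmoid'")
        if self.activation == "sigmoid" and self.eta <= 0:
            raise ValueError("sigmoid activation requires eta > 0")


def linear_drift_matrix(p: WCParameters) -> np.ndarray:
    """Drift matrix of the linear (zero-delay) model d[E,I]/dt = A [E,I]."""
    b = p.beta
    return np.array([
        [-1.0 / p.omega_e, -b * p.w_ie / p.omega_e],
        [b * p.w_ei / p.omega_i, -(1.0 + b * p.w_ii) / p.omega_i],
    ])


def linear_peak_frequency(p: WCParameters) -> float:
    """Oscillation frequency Im(eig)/2*pi of the linear model (Hz).

    Returns 0 when the eigenvalues are real (no oscillatory mode).
    """
    eig = np.linalg.eigvals(linear_drift_matrix(p))
    return float(np.max(np.abs(eig.imag)) / (2.0 * math.pi))


def simulate_wc(p: WCParameters, dt: float = 1e-3, duration: float = 10.0,
                seed: int = 0, burn_in: float = 10.0):
    """Euler-Maruyama simulation of the (possibly delayed) stochastic model.

    Delay history before t = 0 is held constant at the initial state; delays
    are rounded to the nearest multiple of ``dt``. The linear variant forces
    zero delays. Raises on instability (|E| or |I| above 1e6).

    Returns ``(E, I)`` as :class:`TimeSeries` with the burn-in removed.
    """
    if dt >= min(p.omega_e, p.omega_i) / 10.0:
        raise ValueError("dt must be below a tenth of the smallest time constant")
    sigmoid = p.activation == "sigmoid"
    if sigmoid:
        d_ie = int(round(p.delta_ie / dt))
        d_ei = int(round(p.delta_ei / dt))
        d_ii = int(round(p.delta_ii / dt))
    else:
        d_ie = d_ei = d_ii = 0
    rng = np.random.default_rng(seed)
    n = int(round((duration + burn_in) / dt))
    noise_e = rng.standard_normal(n)
    noise_i = rng.standard_normal(n)
    E, I = wc_loop(dt, n, p.omega_e, p.omega_i, p.w_ie, p.w_ei, p.w_ii,
                   p.lambda_e, p.lambda_i, p.zeta, sigmoid, p.beta, p.eta,
                   d_ie, d_ei, d_ii, noise_e, noise_i, 0.0, 0.0)
    if np.isnan(E[0]):
        raise FloatingPointError(f"Wilson-Cowan simulation diverged: {p}")
    skip = int(round(burn_in / dt)) + 1
    return TimeSeries(E[skip:], dt), TimeSeries(I[skip:], dt)


def wc_features(p: WCParameters, dt: float = 1e-3, n_repeats: int = 5,
                repeat_duration: float = 1000.0,
                percentiles: np.ndarray = DEFAULT_PERCENTILES,
                min_duration: float = 0.1, seed: int = 0,
                smooth_span: float = 0.005):
    """Repeat-averaged PSD and burst duration profile of the E population.

    The envelope is the smoothed modulus of the analytic signal of E. Both
    features are averaged over ``n_repeats`` independent repeats.
    """
    freqs = None
    powers, durs, thresholds = [], [], []
    for r in range(n_repeats):
        E, _ = simulate_wc(p, dt=dt, duration=repeat_duration, seed=seed * 1000 + r)
        spec = psd(E)
        freqs = spec.freqs
        powers.append(spec.power)
        env = hilbert_envelope(E, smooth_span=smooth_span)
        prof = burst_profiles(env, percentiles, min_duration)
        durs.append(prof.mean_duration)
        thresholds.append(prof.thresholds)
    power = np.mean(powers, axis=0)
    durs = np.array(durs)
    with np.errstate(invalid="ignore"):
        mean_dur = np.nanmean(durs, axis=0)
        n_ok = np.sum(np.isfinite(durs), axis=0)
        if n_repeats > 1:
            sem_dur = np.nanstd(durs, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
        else:
            sem_dur = np.full_like(mean_dur, np.nan)
    return (SpectralDensity(freqs, power),
            ThresholdProfile(np.asarray(percentiles, dtype=float),
                             np.mean(thresholds, axis=0), mean_dur, sem_dur))
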