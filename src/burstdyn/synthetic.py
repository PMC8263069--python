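"""Synthetic data generators with known ground truth.

Every input class the toolkit consumes can be generated here: linear ARMA
controls, 1/f (pink) noise controls, OU / polynomial envelope models,
Rayleigh envelopes, and linear or delayed-sigmoid Wilson-Cowan signals. All
generators are pure functions of (parameters, seed), so fixtures are fully
reproducible and carry their ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .envelope_models import (PolynomialDrift, ou_exact_path, simulate_ou,
                              simulate_polynomial, synthesize_oscillation)
from .features import bandpass_filter
from .neural_mass import WCParameters, simulate_wc
from .types import Envelope, TimeSeries

__all__ = ["ARMASpec", "gen_arma", "gen_pink_noise", "fixture_suite",
           "FixtureManifest", "CUBIC_SHOULDER", "CUBIC_SHOULDER_ZETA",
           "POLY5_SHOULDER", "POLY5_SHOULDER_ZETA"]

#: monostable cubic drift with a high-amplitude "shoulder": strong pull
#: towards ~0.66 at low amplitude, and a near-zero dip of the drift around
#: x ~ 1.9 (factored form -0.4*(x-0.6)*((x-1.9)^2+0.05)) where attraction
#: almost vanishes, letting the envelope linger at elevated levels.
CUBIC_SHOULDER = np.array([0.8784, -2.376, 1.76, -0.4])
CUBIC_SHOULDER_ZETA = 0.5

#: fifth-degree drift with the same character, used for passage-method tests
POLY5_SHOULDER = np.array([1.0, -2.2, 1.35, -0.3, 0.02, -0.002])
POLY5_SHOULDER_ZETA = 0.8


@dataclass(frozen=True)
class ARMASpec:
    """ARMA(p, q): y_n = sum_i a_i y_{n-i} + sum_i b_i eps_{n-i}."""

    ar: tuple = ()
    ma: tuple = (1.0,)
    noise_sd: float = 1.0

    def __post_init__(self):
        ar = tuple(float(a) for a in self.ar)
        ma = tuple(float(b) for b in self.ma)
        if not ma:
            raise ValueError("need at least b_0")
        # stationarity: roots of 1 - a_1 z - ... - a_p z^p outside unit circle
        if ar:
            poly = np.concatenate(([1.0], -np.asarray(ar)))
            roots = np.roots(poly[::-1])
            if np.any(np.abs(roots) <= 1.0 + 1e-12):
                raise ValueError("AR polynomial roots must lie outside the unit circle")
        object.__setattr__(self, "ar", ar)
        object.__setattr__(self, "ma", ma)


def gen_arma(spec: ARMASpec, duration: float, dt: float, seed: int = 0,
             burn_in_samples: int = 1000) -> TimeSeries:
    """Simulate a stationary ARMA process (1000-sample burn-in discarded)."""
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, spec.noise_sd, n + burn_in_samples)
    a = np.concatenate(([1.0], -np.asarray(spec.ar))) if spec.ar else np.array([1.0])
    y = lfilter(np.asarray(spec.ma), a, eps)
    return TimeSeries(y[burn_in_samples:], dt)


def gen_pink_noise(duration: float, dt: float, seed: int = 0,
                   band: tuple | None = None) -> TimeSeries:
    """1/f (pink) noise by spectral shaping; optionally band-pass filtered.

    Gaussian white noise is shaped in the frequency domain with amplitude
    proportional to f^{-1/2} (power ~ 1/f), unit variance. ``band=(lo, hi)``
    additionally applies the standard zero-phase band-pass.
    """
    n = int(round(duration / dt))
    if n < 2 ** 10:
        raise ValueError("need at least 2^10 samples")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** -0.5
    shape[0] = 0.0
    y = np.fft.irfft(spec * shape, n=n)
    y = (y - y.mean()) / y.std()
    ts = TimeSeries(y, dt)
    if band is not None:
        ts = bandpass_filter(ts, band[0], band[1])
    return ts


@dataclass(frozen=True)
class FixtureManifest:
    """Named datasets plus the ground truth that generated them."""

    seed: int
    datasets: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)


def fixture_suite(seed: int = 0, duration: float = 200.0,
                  dt: float = 1e-3) -> FixtureManifest:
    """Deterministic suite of fixtures covering every input class.

    Includes OU envelopes (theta in {0.5, 1, 2}, zeta = 1), the cubic and
    fifth-degree shoulder models, a Rayleigh-like envelope, linear and
    delayed-sigmoid Wilson-Cowan signals, an AR(1) control, and a pink-noise
    control. Durations default to a desk-scale 200 s; pass a longer duration
    for validation-grade statistics.
    """
    datasets: dict = {}
    truth: dict = {}
    for i, theta in enumerate((0.5, 1.0, 2.0)):
        name = f"ou_theta_{theta:g}"
        datasets[name] = simulate_ou(theta, 1.0, dt, duration, seed=seed + i)
        truth[name] = {"model": "ou", "theta": theta, "zeta": 1.0, "dt": dt}
    cubic = PolynomialDrift(CUBIC_SHOULDER)
    datasets["cubic_shoulder"] = simulate_polynomial(cubic, CUBIC_SHOULDER_ZETA,
                                                     dt, duration, seed=seed + 10)
    truth["cubic_shoulder"] = {"model": "poly", "coeffs": CUBIC_SHOULDER.tolist(),
                               "zeta": CUBIC_SHOULDER_ZETA, "dt": dt}
    poly5 = PolynomialDrift(POLY5_SHOULDER)
    datasets["poly5_shoulder"] = simulate_polynomial(poly5, 0.8, dt, duration,
                                                     seed=seed + 11)
    truth["poly5_shoulder"] = {"model": "poly", "coeffs": POLY5_SHOULDER.tolist(),
                               "zeta": 0.8, "dt": dt}
    # Rayleigh: its Euler step is singular at 0, so build the envelope as
    # the modulus of two independent centered OU components (equivalent)
    n = int(round(duration / dt))
    e1 = ou_exact_path(1.0, 1.0, dt, n, seed=seed + 12)
    e2 = ou_exact_path(1.0, 1.0, dt, n, seed=seed + 13)
    datasets["rayleigh"] = Envelope(np.hypot(e1, e2), dt)
    truth["rayleigh"] = {"model": "rayleigh", "theta": 1.0, "zeta": 1.0, "dt": dt}
    wc_lin = WCParameters(w_ie=4.0, w_ei=4.0, w_ii=0.5, omega_e=0.012,
                          omega_i=0.012, zeta=1.0, activation="linear",
                          beta=0.6)
    E, _ = simulate_wc(wc_lin, dt=dt, duration=duration, seed=seed + 20)
    datasets["wc_linear"] = E
    truth["wc_linear"] = {"model": "wc", "params": wc_lin}
    wc_sig = WCParameters(w_ie=3.0, w_ei=5.0, w_ii=1.0, lambda_e=1.0,
                          lambda_i=0.2, omega_e=0.015, omega_i=0.015,
                          zeta=0.3, activation="sigmoid", beta=4.0, eta=1.5,
                          delta_ei=0.006, delta_ie=0.006, delta_ii=0.004)
    E2, _ = simulate_wc(wc_sig, dt=dt, duration=duration, seed=seed + 21)
    datasets["wc_sigmoid_delays"] = E2
    truth["wc_sigmoid_delays"] = {"model": "wc", "params": wc_sig}
    ar1 = ARMASpec(ar=(0.9,))
    datasets["ar1_control"] = gen_arma(ar1, duration, dt, seed=seed + 30)
    truth["ar1_control"] = {"model": "arma", "ar": [0.9], "ma": [1.0]}
    datasets["pink_control"] = gen_pink_noise(duration, dt, seed=seed + 31)
    truth["pink_control"] = {"model": "pink"}
    return FixtureManifest(seed=seed, datasets=datasets, ground_truth=truth)
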