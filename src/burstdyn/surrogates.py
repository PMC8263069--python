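"""Linear surrogate time series: FT, IAAFT, and gradual wavelet reconstruction.

Surrogates preserve the linear structure of a signal (power spectrum; for
IAAFT also the value distribution) while destroying non-linear structure,
providing the null ensemble against which burst-duration non-linearity is
measured. Gradual wavelet reconstruction (GWR) interpolates between IAAFT
surrogates (rho = 0) and the data itself (rho = 1) by fixing the largest
wavelet coefficients covering an energy fraction rho, which makes the test
robust to nonstationarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt

from .features import burst_profiles, hilbert_envelope
from .types import Envelope, ThresholdProfile, TimeSeries, DEFAULT_PERCENTILES

__all__ = [
    "GWRConfig",
    "SurrogateEnsemble",
    "ft_surrogate",
    "iaaft_surrogate",
    "gwr_surrogate",
    "surrogate_ensemble",
    "surrogate_profile",
]

IAAFT_TOL = 1e-6  # relative change of spectral mismatch between iterations


@dataclass(frozen=True)
class GWRConfig:
    """Configuration of gradual-wavelet-reconstruction surrogates.

    rho : fraction of total wavelet energy fixed (0 = IAAFT, 1 = data)
    wavelet : PyWavelets name; default 8-tap least-asymmetric Daubechies
    n_levels : decomposition depth; default floor(log2 N) - 2, capped by
        the wavelet's maximum usable level
    """

    rho: float
    wavelet: str = "sym4"
    n_levels: int | None = None
    max_iaaft_iter: int = 100
    tol: float = IAAFT_TOL

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.n_levels is not None and self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


@dataclass(frozen=True)
class SurrogateEnsemble:
    realizations: list
    rho: float
    seeds: list

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("realization seeds must be distinct")


def _child_rng(seed: int, index: int) -> np.random.Generator:
    """Derived stream for realization ``index`` of ensemble ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def ft_surrogate(ts: TimeSeries, seed: int = 0) -> TimeSeries:
    """Phase-randomized surrogate: Fourier amplitudes kept, phases uniform.

    Phases are conjugate-symmetric so the output is real; the DC and (for
    even length) Nyquist bins are left untouched.
    """
    if len(ts) < 4:
        raise ValueError("need at least 4 samples")
    rng = _child_rng(seed, 0)
    spec = np.fft.rfft(ts.values)
    phases = rng.uniform(0.0, 2.0 * math.pi, len(spec))
    phases[0] = 0.0
    if len(ts) % 2 == 0:
        phases[-1] = 0.0
    surr = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=len(ts))
    return TimeSeries(surr, ts.dt)


def _iaaft_core(target_sorted: np.ndarray, target_amp: np.ndarray,
                init: np.ndarray, max_iter: int, tol: float):
    """Iterated amplitude-adjusted FT from a given starting series.

    Alternates imposing the target Fourier amplitude spectrum and the target
    value multiset (rank remap) until the relative spectral mismatch changes
    by less than ``tol`` or ``max_iter`` is reached. The final step is always
    the rank remap, so the value multiset match is exact.
    """
    n = len(init)
    y = init
    prev_err = np.inf
    it = 0
    amp_norm = np.linalg.norm(target_amp)
    out = np.empty(n)
    for it in range(1, max_iter + 1):
        spec = np.fft.rfft(y)
        mag = np.abs(spec)
        err = np.linalg.norm(mag - target_amp) / amp_norm if amp_norm > 0 else 0.0
        np.maximum(mag, 1e-300, out=mag)
        y = np.fft.irfft(spec * (target_amp / mag), n=n)
        order = np.argsort(y, kind="stable")
        out[order] = target_sorted  # rank remap: exact value multiset
        y = out.copy()
        if abs(prev_err - err) < tol * max(err, 1e-300):
            break
        prev_err = err
    return y, it


def iaaft_surrogate(ts: TimeSeries, seed: int = 0, max_iter: int = 100,
                    tol: float = IAAFT_TOL, return_iterations: bool = False):
    """IAAFT surrogate: exact value multiset, approximate power spectrum.

    Starts from a random permutation of the data. Non-convergence within
    ``max_iter`` is not an error; pass ``return_iterations=True`` to get the
    iteration count alongside the surrogate.
    """
    if len(ts) < 4:
        raise ValueError("need at least 4 samples")
    rng = _child_rng(seed, 0)
    target_sorted = np.sort(ts.values)
    target_amp = np.abs(np.fft.rfft(ts.values))
    init = rng.permutation(ts.values)
    y, it = _iaaft_core(target_sorted, target_amp, init, max_iter, tol)
    surr = TimeSeries(y, ts.dt)
    return (surr, it) if return_iterations else surr


def _swt_levels(n: int, config: GWRConfig) -> int:
    levels = config.n_levels
    if levels is None:
        levels = max(1, int(math.floor(math.log2(n))) - 2)
    return min(levels, 10)


def gwr_surrogate(ts: TimeSeries, config: GWRConfig, seed: int = 0) -> TimeSeries:
    """Gradual-wavelet-reconstruction surrogate.

    A stationary (undecimated, energy-normalized) wavelet transform of the
    data is taken; squared coefficients are ranked from largest to smallest
    irrespective of scale and position and fixed until the cumulative energy
    reaches ``rho`` times the total. Free coefficients at each scale are
    IAAFT-randomized (fixed positions re-imposed), the transform is
    inverted, and a final IAAFT pass on the whole series enforces the exact
    value multiset and the spectrum. ``rho = 1`` returns the data exactly;
    ``rho = 0`` reduces to an IAAFT surrogate.
    """
    n = len(ts)
    levels = _swt_levels(n, config)
    if n < 2 ** levels:
        raise ValueError("series shorter than 2^n_levels")
    rng = _child_rng(seed, 1)

    # reflect-pad to a multiple of 2^levels for the undecimated transform
    block = 2 ** levels
    pad = (-n) % block
    x = np.concatenate([ts.values, ts.values[-2:-(pad + 2):-1]]) if pad else ts.values

    # undecimated transform, energy-preserving: [cA_J, cD_J, ..., cD_1]
    bands = pywt.swt(x, config.wavelet, level=levels, trim_approx=True, norm=True)
    flat = np.concatenate(bands)
    energy = flat ** 2
    total = energy.sum()
    order = np.argsort(energy)[::-1]
    csum = np.cumsum(energy[order])
    target = config.rho * total
    # number fixed: smallest count whose cumulative energy reaches rho*total
    n_fix = int(np.searchsorted(csum, target, side="left")) + 1 if config.rho > 0 else 0
    n_fix = min(n_fix, len(flat))
    fixed_mask_flat = np.zeros(len(flat), dtype=bool)
    fixed_mask_flat[order[:n_fix]] = True

    if config.rho >= 1.0 or n_fix == len(flat):
        return TimeSeries(ts.values.copy(), ts.dt)

    # split the flat mask back into bands and IAAFT-randomize each band
    out_bands = []
    pos = 0
    for b in bands:
        m = fixed_mask_flat[pos:pos + len(b)]
        pos += len(b)
        nb = b.copy()
        if (~m).sum() > 4:
            sub_init = rng.permutation(b)
            y, _ = _iaaft_core(np.sort(b), np.abs(np.fft.rfft(b)), sub_init,
                               config.max_iaaft_iter, config.tol)
            nb[~m] = y[~m]
        out_bands.append(nb)

    candidate = pywt.iswt(out_bands, config.wavelet, norm=True)[:n]

    # global IAAFT pass seeded from the candidate (no re-shuffle): for
    # rho = 1 the candidate equals the data, so this is an exact fixed point
    target_sorted = np.sort(ts.values)
    target_amp = np.abs(np.fft.rfft(ts.values))
    y, _ = _iaaft_core(target_sorted, target_amp, candidate,
                       config.max_iaaft_iter, config.tol)
    return TimeSeries(y, ts.dt)


def gwr_fixed_energy_fraction(ts: TimeSeries, config: GWRConfig) -> float:
    """Energy fraction actually covered by the fixed coefficients (>= rho)."""
    n = len(ts)
    levels = _swt_levels(n, config)
    block = 2 ** levels
    pad = (-n) % block
    x = np.concatenate([ts.values, ts.values[-2:-(pad + 2):-1]]) if pad else ts.values
    bands = pywt.swt(x, config.wavelet, level=levels, trim_approx=True, norm=True)
    energy = np.concatenate(bands) ** 2
    total = energy.sum()
    if config.rho == 0:
        return 0.0
    srt = np.sort(energy)[::-1]
    csum = np.cumsum(srt)
    n_fix = int(np.searchsorted(csum, config.rho * total, side="left")) + 1
    return float(csum[min(n_fix, len(srt)) - 1] / total)


def surrogate_ensemble(ts: TimeSeries, n: int = 19, method: str = "iaaft",
                       rho: float = 0.0, seed: int = 0,
                       config: GWRConfig | None = None,
                       max_iter: int = 100) -> SurrogateEnsemble:
    """Generate ``n`` surrogate realizations with derived per-realization seeds."""
    if config is None:
        config = GWRConfig(rho=rho)
    reals, seeds = [], []
    for i in range(n):
        child = seed * 100003 + i  # documented counter scheme
        seeds.append(child)
        if method == "ft":
            reals.append(ft_surrogate(ts, seed=child))
        elif method == "iaaft":
            reals.append(iaaft_surrogate(ts, seed=child, max_iter=max_iter))
        elif method == "gwr":
            reals.append(gwr_surrogate(ts, config, seed=child))
        else:
            raise ValueError(f"unknown surrogate method {method!r}")
    return SurrogateEnsemble(reals, config.rho if method == "gwr" else 0.0, seeds)


def surrogate_profile(ts: TimeSeries, n: int = 19, rho: float = 0.0,
                      percentiles: np.ndarray = DEFAULT_PERCENTILES,
                      min_duration: float = 0.1, seed: int = 0,
                      method: str | None = None,
                      smooth_span: float = 0.005) -> ThresholdProfile:
    """Across-realization mean burst duration profile of linear surrogates.

    ``ts`` must already be the filtered signal: surrogates reproduce its
    spectrum and are not re-filtered. Each realization's envelope and profile
    are computed without segmentation; the returned profile carries the
    across-realization mean and SEM (sample SD / sqrt(n)).
    """
    if method is None:
        method = "iaaft" if rho == 0 else "gwr"
    ens = surrogate_ensemble(ts, n=n, method=method, rho=rho, seed=seed)
    durs, amps, rates = [], [], []
    thresholds = None
    for real in ens.realizations:
        env = hilbert_envelope(real, smooth_span=smooth_span)
        prof = burst_profiles(env, percentiles, min_duration)
        durs.append(prof.mean_duration)
        amps.append(prof.mean_amplitude)
        rates.append(prof.rate)
        thresholds = prof.thresholds if thresholds is None else thresholds + prof.thresholds
    durs = np.array(durs)
    amps = np.array(amps)
    rates = np.array(rates)
    with np.errstate(invalid="ignore"):
        mean_dur = np.nanmean(durs, axis=0)
        sem_dur = np.nanstd(durs, axis=0, ddof=1) / np.sqrt(np.sum(np.isfinite(durs), axis=0))
        mean_amp = np.nanmean(amps, axis=0)
        sem_amp = np.nanstd(amps, axis=0, ddof=1) / np.sqrt(np.sum(np.isfinite(amps), axis=0))
    return ThresholdProfile(np.asarray(percentiles, dtype=float), thresholds / n,
                            mean_dur, sem_dur, mean_amp, sem_amp,
                            rates.mean(axis=0), None)
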