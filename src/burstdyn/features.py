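"""Feature extraction: filtering, envelopes, bursts, and threshold profiles.

A raw single-channel signal is band-pass filtered around its beta-band
spectral peak, z-scored, converted to an amplitude envelope (smoothed modulus
of the analytic signal), and summarized as average burst duration / amplitude
/ rate across a grid of envelope-percentile thresholds.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .types import (AmplitudePDF, BurstSet, Envelope, SpectralDensity,
                    ThresholdProfile, TimeSeries, DEFAULT_PERCENTILES)

__all__ = [
    "bandpass_filter",
    "find_spectral_peak",
    "prepare_pair",
    "hilbert_envelope",
    "detect_bursts",
    "burst_profiles",
    "burst_rate_profile",
    "envelope_pdf",
    "psd",
    "segment_envelope",
    "segment_features",
    "supra_threshold_runs",
]

MIN_BURST_DURATION = 0.1  # seconds; the conventional 100 ms criterion


def psd(ts: TimeSeries, window_s: float = 1.0) -> SpectralDensity:
    """Welch power spectral density (Hann windows, 50% overlap).

    The window length defaults to 1 s; it is clipped to the signal length so
    short signals degrade to a single periodogram.
    """
    nperseg = min(int(round(window_s / ts.dt)), len(ts))
    freqs, power = signal.welch(ts.values, fs=ts.fs, window="hann",
                                nperseg=nperseg, noverlap=nperseg // 2)
    return SpectralDensity(freqs, power)


def find_spectral_peak(ts: TimeSeries, lo: float = 13.0, hi: float = 35.0,
                       window_s: float = 1.0) -> float:
    """Frequency of the PSD maximum strictly inside [lo, hi] Hz.

    Raises
    ------
    ValueError
        If the in-band maximum sits on the band edge ("no beta peak"):
        a peak on the edge means the true maximum lies outside the band.
    """
    spec = psd(ts, window_s=window_s)
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 3:
        raise ValueError("no beta peak: band narrower than spectral resolution")
    f_band = spec.freqs[mask]
    p_band = spec.power[mask]
    i = int(np.argmax(p_band))
    if i == 0 or i == len(f_band) - 1:
        raise ValueError("no beta peak: spectral maximum on the band edge")
    return float(f_band[i])


def bandpass_filter(ts: TimeSeries, lo: float, hi: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    return TimeSeries(signal.sosfiltfilt(sos, ts.values), ts.dt)


def zscore(ts: TimeSeries) -> TimeSeries:
    sd = np.std(ts.values)
    if sd == 0:
        raise ValueError("cannot z-score a constant signal")
    return TimeSeries((ts.values - np.mean(ts.values)) / sd, ts.dt)


def prepare_pair(ts_on: TimeSeries, ts_off: TimeSeries, band_lo: float = 13.0,
                 band_hi: float = 35.0, half_width: float = 3.0):
    """Filter an ON/OFF pair around the OFF-state beta peak and z-score each.

    The peak is located in the OFF-state spectrum within [band_lo, band_hi];
    both series are band-pass filtered to peak +/- half_width and then
    individually z-scored (mean 0, sd 1).

    Returns
    -------
    (TimeSeries, TimeSeries, float)
        Filtered, z-scored ON and OFF series, and the peak frequency in Hz.
    """
    if not np.isclose(ts_on.dt, ts_off.dt):
        raise ValueError("ON and OFF series must share the sampling rate")
    peak = find_spectral_peak(ts_off, band_lo, band_hi)
    out = []
    for ts in (ts_on, ts_off):
        filt = bandpass_filter(ts, peak - half_width, peak + half_width)
        out.append(zscore(filt))
    return out[0], out[1], peak


def hilbert_envelope(ts: TimeSeries, smooth_span: float = 0.005) -> Envelope:
    """Smoothed modulus of the analytic signal.

    The magnitude of the discrete Hilbert analytic signal is smoothed with a
    centered moving average of span ``round(smooth_span / dt)`` samples
    (reflected at the edges). ``smooth_span=0`` disables smoothing.
    """
    n = len(ts)
    analytic = signal.hilbert(ts.values)
    env = np.abs(analytic)
    span = int(round(smooth_span / ts.dt))
    if span > 1:
        env = uniform_filter1d(env, size=span, mode="reflect")
    # numerical guard: the modulus is >= 0 but smoothing is FP arithmetic
    np.clip(env, 0.0, None, out=env)
    return Envelope(env[:n], ts.dt)


def supra_threshold_runs(values: np.ndarray, threshold: float):
    """Maximal runs of consecutive samples with ``values > threshold``.

    Returns ``(starts, ends)`` as half-open index ranges. Runs touching
    either end of the array are kept. Ties (== threshold) count as below.
    """
    mask = values > threshold
    if not mask.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(values)]))
    return starts.astype(np.int64), ends.astype(np.int64)


def detect_bursts(env: Envelope, threshold: float,
                  min_duration: float = MIN_BURST_DURATION) -> BurstSet:
    """Detect bursts: envelope strictly above ``threshold`` for at least
    ``min_duration`` seconds.

    Burst duration is ``run_length * dt`` and burst amplitude is the envelope
    maximum within the run.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    starts, ends = supra_threshold_runs(env.values, threshold)
    if min_duration > 0:
        keep = (ends - starts) * env.dt >= min_duration
        starts, ends = starts[keep], ends[keep]
    amps = np.array([env.values[s:e].max() for s, e in zip(starts, ends)])
    return BurstSet(np.column_stack([starts, ends]) if len(starts)
                    else np.empty((0, 2), np.int64),
                    env.dt, float(threshold), amps)


def _profile_arrays(env_values: np.ndarray, dt: float, thresholds: np.ndarray,
                    min_duration: float, with_amplitude: bool = True):
    """Per-threshold burst statistics. NaN marks thresholds with no burst."""
    n_thr = len(thresholds)
    mean_dur = np.full(n_thr, np.nan)
    sem_dur = np.full(n_thr, np.nan)
    mean_amp = np.full(n_thr, np.nan)
    sem_amp = np.full(n_thr, np.nan)
    rate = np.zeros(n_thr)
    n_bursts = np.zeros(n_thr)
    total_t = len(env_values) * dt
    min_len = 0 if min_duration <= 0 else int(np.ceil(min_duration / dt))
    for k, thr in enumerate(thresholds):
        starts, ends = supra_threshold_runs(env_values, thr)
        lengths = ends - starts
        if min_len:
            keep = lengths * dt >= min_duration
            starts, ends, lengths = starts[keep], ends[keep], lengths[keep]
        m = len(lengths)
        n_bursts[k] = m
        rate[k] = m / total_t
        if m == 0:
            continue
        dur = lengths * dt
        mean_dur[k] = dur.mean()
        sem_dur[k] = dur.std(ddof=1) / np.sqrt(m) if m > 1 else np.nan
        if with_amplitude:
            # reduceat over interleaved [start, end) boundaries; a final
            # end == len(values) is dropped (the last segment then runs to
            # the array end, which is that run's slice anyway)
            bounds = np.column_stack([starts, ends]).ravel()
            if bounds[-1] == len(env_values):
                bounds = bounds[:-1]
            amps = np.maximum.reduceat(env_values, bounds)[::2]
            mean_amp[k] = amps.mean()
            sem_amp[k] = amps.std(ddof=1) / np.sqrt(m) if m > 1 else np.nan
    return mean_dur, sem_dur, mean_amp, sem_amp, rate, n_bursts


def burst_profiles(env: Envelope, percentiles: np.ndarray = DEFAULT_PERCENTILES,
                   min_duration: float = MIN_BURST_DURATION) -> ThresholdProfile:
    """Average burst duration/amplitude/rate across percentile thresholds.

    For each percentile rank the threshold is the empirical percentile of the
    envelope (linear interpolation between order statistics). Percentiles
    with zero qualifying bursts carry NaN, never 0.
    """
    percentiles = np.asarray(percentiles, dtype=float)
    if np.ptp(env.values) == 0:
        raise ValueError("degenerate envelope: constant values")
    thresholds = np.quantile(env.values, percentiles)
    md, sd, ma, sa, rate, nb = _profile_arrays(env.values, env.dt, thresholds,
                                               min_duration)
    return ThresholdProfile(percentiles, thresholds, md, sd, ma, sa, rate, nb)


def burst_rate_profile(env: Envelope, percentiles: np.ndarray = DEFAULT_PERCENTILES,
                       min_duration: float = 0.0) -> np.ndarray:
    """Bursts per second at each percentile threshold.

    With ``min_duration=0`` the identity ``rate * mean_duration = fraction of
    samples above threshold`` holds exactly per realization, so the rate
    profile carries the same information as the duration profile.
    """
    prof = burst_profiles(env, percentiles, min_duration)
    return prof.rate


def envelope_pdf(env: Envelope, n_bins: int = 50) -> AmplitudePDF:
    """Normalized histogram estimate of the envelope amplitude density."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    density, edges = np.histogram(env.values, bins=n_bins, density=True)
    return AmplitudePDF(edges, density)


def segment_envelope(env: Envelope, n_segments: int = 5):
    """Split an envelope into contiguous equal-length segments.

    The trailing remainder (fewer than ``len // n_segments`` samples) is
    dropped, matching the convention of computing per-segment features for
    SEM estimation and paired tests.
    """
    seg_len = len(env) // n_segments
    if seg_len < 2:
        raise ValueError("envelope too short for the requested segmentation")
    return [Envelope(env.values[i * seg_len:(i + 1) * seg_len], env.dt)
            for i in range(n_segments)]


def segment_features(env: Envelope, n_segments: int = 5,
                     percentiles: np.ndarray = DEFAULT_PERCENTILES,
                     min_duration: float = MIN_BURST_DURATION,
                     n_bins: int = 50):
    """Per-segment threshold profiles and amplitude PDFs.

    Returns ``(profiles, pdfs)``, one entry per segment. Thresholds and
    histogram bins are computed per segment from that segment's own values.
    """
    segs = segment_envelope(env, n_segments)
    profiles = [burst_profiles(s, percentiles, min_duration) for s in segs]
    pdfs = [envelope_pdf(s, n_bins) for s in segs]
    return profiles, pdfs
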