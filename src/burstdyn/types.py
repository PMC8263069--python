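"""Core containers for burst-dynamics analysis.

The analysis pipeline passes around a small set of typed arrays: a uniformly
sampled signal (:class:`TimeSeries`), its non-negative amplitude envelope
(:class:`Envelope`), detected supra-threshold events (:class:`BurstSet`),
and the central summary statistic of the toolkit, the average burst duration
profile across envelope-percentile thresholds (:class:`ThresholdProfile`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Envelope",
    "BurstSet",
    "ThresholdProfile",
    "SpectralDensity",
    "AmplitudePDF",
    "DEFAULT_PERCENTILES",
]

#: 20th to 95th percentile in steps of 5%, the standard threshold grid.
DEFAULT_PERCENTILES = np.round(np.arange(0.20, 0.951, 0.05), 10)


def _as_1d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    return arr


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Signal samples (arbitrary units).
    dt : float
        Seconds per sample, > 0.
    """

    values: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_1d_float(self.values))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if len(self.values) < 2:
            raise ValueError("need at least 2 samples")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples * dt)."""
        return len(self.values) * self.dt

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Envelope:
    """Non-negative instantaneous amplitude track of an oscillatory signal."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_1d_float(self.values))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope must be finite")
        if np.any(self.values < 0):
            raise ValueError("envelope must be non-negative")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BurstSet:
    """Supra-threshold events of an envelope.

    ``intervals`` holds half-open sample index ranges ``[start, end)``,
    disjoint and sorted. Durations are ``(end - start) * dt`` and the burst
    amplitude is the envelope maximum within the run.
    """

    intervals: np.ndarray  # (n, 2) int
    dt: float
    threshold: float
    amplitudes: np.ndarray = field(default=None)  # peak envelope per burst

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if len(iv):
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("intervals must satisfy end > start")
            if np.any(np.diff(iv[:, 0]) <= 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("intervals must be sorted and disjoint")
        if self.amplitudes is not None:
            object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))

    @property
    def durations(self) -> np.ndarray:
        """Burst durations in seconds."""
        if len(self.intervals) == 0:
            return np.empty(0)
        return (self.intervals[:, 1] - self.intervals[:, 0]) * self.dt

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ThresholdProfile:
    """Average burst statistics as a function of envelope-percentile threshold.

    Percentile ranks are in [0, 1); thresholds are the corresponding
    empirical envelope amplitudes. Entries where no qualifying burst exists
    are NaN (missing), never zero.
    """

    percentiles: np.ndarray
    thresholds: np.ndarray
    mean_duration: np.ndarray  # seconds
    sem_duration: np.ndarray = None
    mean_amplitude: np.ndarray = None
    sem_amplitude: np.ndarray = None
    rate: np.ndarray = None  # bursts per second
    n_bursts: np.ndarray = None

    def __post_init__(self):
        p = _as_1d_float(self.percentiles)
        if np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing")
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("percentile ranks must lie in [0, 1)")
        object.__setattr__(self, "percentiles", p)
        object.__setattr__(self, "thresholds", _as_1d_float(self.thresholds))
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be non-decreasing")
        for name in ("mean_duration", "sem_duration", "mean_amplitude",
                     "sem_amplitude", "rate", "n_bursts"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != p.shape:
                    raise ValueError(f"{name} must match percentile grid")
                object.__setattr__(self, name, v)

    def same_grid(self, other: "ThresholdProfile", atol: float = 1e-12) -> bool:
        return (len(self.percentiles) == len(other.percentiles)
                and np.allclose(self.percentiles, other.percentiles, atol=atol))

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "percentile": self.percentiles,
            "threshold": self.thresholds,
            "mean_duration_s": self.mean_duration,
        }
        for key, name in [("sem_duration", "sem_duration_s"),
                          ("mean_amplitude", "mean_amplitude"),
                          ("sem_amplitude", "sem_amplitude"),
                          ("rate", "rate_hz"), ("n_bursts", "n_bursts")]:
            v = getattr(self, key)
            cols[name] = v if v is not None else np.full_like(self.percentiles, np.nan)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThresholdProfile":
        def col(name):
            return df[name].to_numpy(dtype=float) if name in df else None

        return cls(
            percentiles=df["percentile"].to_numpy(dtype=float),
            thresholds=df["threshold"].to_numpy(dtype=float),
            mean_duration=df["mean_duration_s"].to_numpy(dtype=float),
            sem_duration=col("sem_duration_s"),
            mean_amplitude=col("mean_amplitude"),
            sem_amplitude=col("sem_amplitude"),
            rate=col("rate_hz"),
            n_bursts=col("n_bursts"),
        )


@dataclass(frozen=True)
class SpectralDensity:
    """One-sided power spectral density (units^2 / Hz)."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = _as_1d_float(self.freqs)
        p = _as_1d_float(self.power)
        if f.shape != p.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)

    def band_power(self, lo: float, hi: float) -> float:
        """Integrated power over [lo, hi] Hz (trapezoidal)."""
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        if mask.sum() < 2:
            raise ValueError("band too narrow for the frequency resolution")
        return float(np.trapezoid(self.power[mask], self.freqs[mask]))


@dataclass(frozen=True)
class AmplitudePDF:
    """Histogram estimate of the envelope amplitude probability density."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        e = _as_1d_float(self.bin_edges)
        d = _as_1d_float(self.density)
        if len(e) != len(d) + 1:
            raise ValueError("need len(bin_edges) == len(density) + 1")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        total = float(np.sum(d * np.diff(e)))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("density must integrate to 1")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "density", d)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
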