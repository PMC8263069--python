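"""Plain-text I/O for time series, envelopes, profiles, and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Envelope, ThresholdProfile, TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "read_profile",
           "write_profile", "write_json_atomic"]


def read_timeseries(path, fs_override: float | None = None) -> TimeSeries:
    """Read a one-column plain-text series.

    The file holds one sample per row; an optional comment header
    ``# fs_hz=<float>`` supplies the sampling rate, which ``fs_override``
    takes precedence over.
    """
    path = Path(path)
    fs = fs_override
    values = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs_hz=") and fs_override is None:
                    fs = float(body.split("=", 1)[1])
                continue
            if line.lower() == "value":  # optional column header
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if fs is None:
        raise ValueError("sampling rate required: add '# fs_hz=' header or pass --fs")
    return TimeSeries(np.asarray(values), 1.0 / fs)


def write_timeseries(path, ts: TimeSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={float(ts.fs)!r}\n")
        for v in ts.values:
            fh.write(f"{float(v)!r}\n")  # repr round-trips doubles exactly


def write_profile(path, profile: ThresholdProfile) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_profile(path) -> ThresholdProfile:
    return ThresholdProfile.from_frame(pd.read_csv(path))


def write_json_atomic(path, obj) -> None:
    """Write JSON via a temporary file and rename (no truncated outputs)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with tmp.open("w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
    tmp.replace(path)


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
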