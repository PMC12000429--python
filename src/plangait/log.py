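"""Sensor-log containers and delimited-text I/O.

The on-disk format is a plain delimited text file with a header row
``t,hip_L,hip_R,knee_L,knee_R,ankle_L,ankle_R,slider_x,fourbar,
I_hip_L,I_hip_R,I_knee_L,I_knee_R`` in SI units and optional ``#``-prefixed
provenance comment lines.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CHANNELS", "ANGLE_CHANNELS", "CURRENT_CHANNELS", "TimeSeriesLog",
           "UniformLog", "read_log_csv", "write_log_csv"]

ANGLE_CHANNELS = (
    "hip_L", "hip_R", "knee_L", "knee_R", "ankle_L", "ankle_R", "fourbar",
)
CURRENT_CHANNELS = ("I_hip_L", "I_hip_R", "I_knee_L", "I_knee_R")
CHANNELS = ANGLE_CHANNELS[:6] + ("slider_x", "fourbar") + CURRENT_CHANNELS


class LogFormatError(ValueError):
    """Raised for malformed sensor logs."""


def _check_channels(timestamps, channels):
    n = len(timestamps)
    for name, series in channels.items():
        if len(series) != n:
            raise LogFormatError(
                f"channel {name!r} length {len(series)} != timestamps length {n}"
            )
    dt = np.diff(timestamps)
    if len(timestamps) >= 2 and not np.all(dt > 0):
        raise LogFormatError("timestamps must be strictly increasing")


@dataclass
class TimeSeriesLog:
    """Raw, non-uniformly sampled multichannel sensor record.

    ``timestamps`` are strictly increasing seconds; every channel is aligned
    to the timestamp vector.  ``metadata`` carries the condition label,
    sampling descriptor, and generator provenance (seed, schedule).
    """

    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        _check_channels(self.timestamps, self.channels)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def median_spacing(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


@dataclass
class UniformLog:
    """Uniformly sampled log on a grid with spacing exactly ``1/rate``.

    ``provenance`` records filter settings applied per channel (empty until
    filtering).
    """

    rate: float
    t0: float
    channels: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise LogFormatError(f"unequal channel lengths: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.rate))


def write_log_csv(log: TimeSeriesLog, path) -> None:
    """Write a sensor log as delimited text with ``#`` provenance comments."""
    df = pd.DataFrame({"t": log.timestamps})
    for name in CHANNELS:
        if name in log.channels:
            df[name] = log.channels[name]
    with open(path, "w") as fh:
        for key, value in log.metadata.items():
            if key == "truth":
                continue  # ground truth is written separately as JSON
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_log_csv(path) -> TimeSeriesLog:
    """Read a delimited sensor log written by :func:`write_log_csv`."""
    metadata: dict = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    try:
                        metadata[key.strip()] = json.loads(value.strip())
                    except json.JSONDecodeError:
                        metadata[key.strip()] = value.strip()
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    if "t" not in df.columns:
        raise LogFormatError("log file missing 't' column")
    channels = {c: df[c].to_numpy() for c in df.columns if c != "t"}
    return TimeSeriesLog(df["t"].to_numpy(), channels, metadata)
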