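"""Signal preparation: resampling, zero-phase filtering, cycle segmentation.

The raw logs are sampled non-uniformly (~600 Hz, control-loop synchronized);
analysis runs on a uniform 1000 Hz grid after linear interpolation, zero-phase
Butterworth low-pass filtering (second-order-sections realization), and
segmentation into gait cycles at ankle-plateau-departure touch-downs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import FilterSettings, ConfigurationError
from .log import TimeSeriesLog, UniformLog, ANGLE_CHANNELS

__all__ = [
    "DetectionError",
    "resample_uniform",
    "lowpass_zero_phase",
    "filter_log",
    "detect_touchdowns",
    "CycleEnsemble",
    "segment_cycles",
]


class InputError(ValueError):
    pass


class DetectionError(RuntimeError):
    """Raised when an event or boundary cannot be located in a trace."""


def resample_uniform(log: TimeSeriesLog, rate: float = 1000.0) -> UniformLog:
    """Linearly interpolate every channel onto a uniform grid at ``rate`` Hz.

    The grid spans [t0, tN] of the input; no extrapolation is performed.
    """
    t = log.timestamps
    if len(t) < 2:
        raise InputError("need at least 2 samples to resample")
    if np.any(np.diff(t) <= 0):
        raise InputError("duplicate or decreasing timestamps")
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    channels = {name: np.interp(grid, t, series) for name, series in log.channels.items()}
    return UniformLog(rate=rate, t0=float(t[0]), channels=channels,
                      metadata=dict(log.metadata))


def lowpass_zero_phase(series, rate: float, order: int = 2, cutoff: float = 20.0):
    """Forward-backward Butterworth low-pass (second-order sections).

    The effective magnitude response is the squared single-pass response and
    the phase shift is zero.  Edges are handled by even-reflection padding
    (scipy's default) of length 3x the section impulse tail.
    """
    if not 0 < cutoff < rate / 2:
        raise ConfigurationError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate/2})")
    if order < 1:
        raise ConfigurationError("filter order must be >= 1")
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    series = np.asarray(series, dtype=float)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(series) <= padlen:
        raise InputError(f"series of length {len(series)} too short for padlen {padlen}")
    return sps.sosfiltfilt(sos, series, padlen=padlen)


def filter_log(log: UniformLog, settings: FilterSettings | None = None) -> UniformLog:
    """Apply the per-channel-group zero-phase filters; record provenance."""
    settings = settings or FilterSettings()
    channels = {}
    provenance = dict(log.provenance)
    for name, series in log.channels.items():
        cutoff = settings.cutoff_for(name)
        channels[name] = lowpass_zero_phase(series, log.rate, settings.order, cutoff)
        provenance[name] = {
            "filter": "butterworth_sos_zero_phase",
            "order": settings.order,
            "cutoff_hz": cutoff,
        }
    return UniformLog(rate=log.rate, t0=log.t0, channels=channels,
                      provenance=provenance, metadata=dict(log.metadata))


def detect_touchdowns(
    ankle_angle,
    rate: float,
    activity_threshold: float = 1.0,
    quiescence_threshold: float = 0.2,
    dwell: float = 0.100,
) -> np.ndarray:
    """Detect touch-downs as the ankle angle's departure from its swing plateau.

    A plateau qualifies when the absolute instantaneous gradient stays below
    ``quiescence_threshold`` (rad/s) for at least ``dwell`` seconds; the
    touch-down is the first subsequent sample whose gradient magnitude
    exceeds ``activity_threshold`` (rad/s).  Returns sample times in seconds
    relative to the first sample.
    """
    ankle_angle = np.asarray(ankle_angle, dtype=float)
    if len(ankle_angle) < 3:
        raise InputError("trace too short for touch-down detection")
    grad = np.abs(np.gradient(ankle_angle) * rate)
    quiet = grad < quiescence_threshold
    active = grad > activity_threshold
    dwell_n = max(1, int(round(dwell * rate)))

    boundaries = []
    run = 0
    armed = False
    for i in range(len(grad)):
        if armed and active[i]:
            boundaries.append(i)
            armed = False
            run = 0
        if quiet[i]:
            run += 1
            if run >= dwell_n:
                armed = True
        else:
            run = 0
    if not boundaries:
        raise DetectionError("no swing plateau departure found in ankle channel")
    return np.asarray(boundaries) / rate


@dataclass
class CycleEnsemble:
    """Cycle-segmented traces on a common %GC grid with ensemble statistics.

    ``cycles[channel]`` has shape (n_cycles, n_points); ``gc_grid`` holds the
    %GC sample positions; ``boundaries`` the touch-down times (seconds,
    length n_cycles + 1); ``mean``/``sd`` per channel on the same grid.
    """

    gc_grid: np.ndarray
    boundaries: np.ndarray
    cycles: dict[str, np.ndarray]
    mean: dict[str, np.ndarray] = field(default_factory=dict)
    sd: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def periods(self) -> np.ndarray:
        return np.diff(self.boundaries)


def segment_cycles(
    log: UniformLog,
    boundaries,
    n_keep: int = 120,
    n_points: int = 1000,
) -> CycleEnsemble:
    """Cut a uniform log into gait cycles and ensemble-average them.

    ``boundaries`` are touch-down times in seconds on the log's clock (as
    returned by :func:`detect_touchdowns`, offset by ``log.t0`` if needed).
    Keeps the first ``n_keep`` complete cycles, resamples each onto a common
    %GC grid of ``n_points`` samples, and computes per-channel ensemble mean
    and SD.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if len(boundaries) < n_keep + 1:
        raise InputError(
            f"need {n_keep + 1} touch-downs for {n_keep} cycles, got {len(boundaries)}"
        )
    boundaries = boundaries[: n_keep + 1]
    gc_grid = np.linspace(0.0, 100.0, n_points, endpoint=False)
    times = log.times
    cycles: dict[str, np.ndarray] = {
        name: np.empty((n_keep, n_points)) for name in log.channels
    }
    for c in range(n_keep):
        t_start, t_end = boundaries[c], boundaries[c + 1]
        sample_times = t_start + gc_grid / 100.0 * (t_end - t_start)
        for name, series in log.channels.items():
            cycles[name][c] = np.interp(sample_times, times, series)
    mean = {name: arr.mean(axis=0) for name, arr in cycles.items()}
    sd = {name: arr.std(axis=0, ddof=0) for name, arr in cycles.items()}
    return CycleEnsemble(
        gc_grid=gc_grid,
        boundaries=boundaries,
        cycles=cycles,
        mean=mean,
        sd=sd,
        provenance=dict(log.provenance),
    )
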