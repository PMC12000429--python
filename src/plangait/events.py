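"""Kinematic gait-event detection on cycle-segmented angle traces.

Five events are located per gait cycle, all expressed in %GC (0 %GC at the
trailing foot's touch-down):

* SAPF - start of ankle plantarflexion: the stance-phase maximum of the
  (dorsiflexion-positive) trailing ankle angle, i.e. the reversal from the
  steady stance dorsiflexion into push-off plantarflexion.
* TO - toe-off: minimum ankle angle within a 40 ms window after the largest
  negative peak of the ankle-angle gradient following SAPF.
* LLTD - leading-leg touch-down: last instant before TO at which the leading
  (contralateral) ankle's absolute gradient exceeds 1 rad/s.
* SHF - start of hip flexion: first instant after peak hip extension at which
  the hip gradient exceeds 1 rad/s.
* SKF - start of knee flexion: first instant in [SHF - 0.2 s, SHF + 0.1 s]
  at which the knee gradient exceeds 1 rad/s.

All detectors operate on filtered traces; a threshold crossing is the first
sample with a strict inequality, and ties break to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AngleConvention
from .prep import CycleEnsemble, DetectionError, InputError

__all__ = [
    "GaitEvents",
    "time_gradient",
    "detect_sapf",
    "detect_to",
    "detect_lltd",
    "detect_shf",
    "detect_skf",
    "extract_events",
]

EVENT_NAMES = ("t_SKF", "t_SHF", "t_SAPF", "t_LLTD", "t_TO")


def time_gradient(series, rate: float):
    """Instantaneous time derivative in units/s.

    Central differences in the interior, one-sided at the edges.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise InputError("need at least 3 samples for a gradient")
    return np.gradient(series) * rate


def _idx_to_gc(idx: int, n: int) -> float:
    return 100.0 * idx / n


def _gc_to_idx(gc: float, n: int) -> int:
    return int(round(gc / 100.0 * n))


def detect_sapf(trailing_ankle, stance_window=(10.0, 90.0)) -> float:
    """%GC of the stance dorsiflexion maximum (plantarflexion onset).

    The search is restricted to ``stance_window`` (%GC) to avoid touch-down
    transients; plateau-valued maxima resolve to their earliest sample.
    """
    trace = np.asarray(trailing_ankle, dtype=float)
    n = len(trace)
    lo, hi = (_gc_to_idx(g, n) for g in stance_window)
    window = trace[lo:hi]
    if len(window) < 3:
        raise DetectionError("stance window too narrow for SAPF")
    k = int(np.argmax(window))
    if k == 0 or k == len(window) - 1:
        raise DetectionError("no dorsiflexion reversal inside the stance window")
    return _idx_to_gc(lo + k, n)


def detect_to(trailing_ankle, rate: float, t_sapf: float, window_s: float = 0.040) -> float:
    """%GC of toe-off: the smallest ankle angle within ``window_s`` after the
    largest negative ankle-gradient peak following SAPF."""
    trace = np.asarray(trailing_ankle, dtype=float)
    n = len(trace)
    grad = time_gradient(trace, rate)
    start = _gc_to_idx(t_sapf, n)
    seg = grad[start:]
    if len(seg) == 0 or np.min(seg) >= 0:
        raise DetectionError("no negative ankle-gradient peak after SAPF")
    g_peak = start + int(np.argmin(seg))
    w_end = min(n, g_peak + int(round(window_s * rate)) + 1)
    k = g_peak + int(np.argmin(trace[g_peak:w_end]))
    return _idx_to_gc(k, n)


def detect_lltd(leading_ankle, rate: float, t_to: float, threshold: float = 1.0) -> float:
    """%GC of leading-leg touch-down: last |gradient| > ``threshold`` before TO.

    The leading leg's trace is the contralateral ankle channel on the same
    cycle clock (no re-segmentation).
    """
    trace = np.asarray(leading_ankle, dtype=float)
    n = len(trace)
    grad = np.abs(time_gradient(trace, rate))
    end = _gc_to_idx(t_to, n)
    above = np.nonzero(grad[:end] > threshold)[0]
    if len(above) == 0:
        raise DetectionError(f"leading ankle gradient never exceeds {threshold} rad/s before TO")
    return _idx_to_gc(int(above[-1]), n)


def detect_shf(hip, rate: float, threshold: float = 1.0) -> float:
    """%GC of the start of hip flexion: first gradient > ``threshold`` after
    peak hip extension (the hip-angle minimum in the flexion-positive
    convention)."""
    trace = np.asarray(hip, dtype=float)
    n = len(trace)
    if np.ptp(trace) == 0:
        raise DetectionError("flat hip trace: no extension peak")
    grad = time_gradient(trace, rate)
    peak = int(np.argmin(trace))
    above = np.nonzero(grad[peak:] > threshold)[0]
    if len(above) == 0:
        raise DetectionError(f"hip gradient never exceeds {threshold} rad/s after peak extension")
    return _idx_to_gc(peak + int(above[0]), n)


def detect_skf(knee, rate: float, t_shf: float, threshold: float = 1.0) -> float:
    """%GC of the start of knee flexion: first knee gradient > ``threshold``
    within [SHF - 0.2 s, SHF + 0.1 s], clamped to the cycle."""
    trace = np.asarray(knee, dtype=float)
    n = len(trace)
    grad = time_gradient(trace, rate)
    center = _gc_to_idx(t_shf, n)
    lo = max(0, center - int(round(0.2 * rate)))
    hi = min(n, center + int(round(0.1 * rate)) + 1)
    above = np.nonzero(grad[lo:hi] > threshold)[0]
    if len(above) == 0:
        raise DetectionError(
            f"knee gradient never exceeds {threshold} rad/s in the SKF search window"
        )
    return _idx_to_gc(lo + int(above[0]), n)


@dataclass
class GaitEvents:
    """Per-cycle event table plus condition-level summary.

    ``per_cycle`` columns: cycle, t_SKF, t_SHF, t_SAPF, t_LLTD, t_TO and the
    derived delta_SAPF_LLTD = t_SAPF - t_LLTD (%GC; negative when SAPF
    precedes LLTD).  ``excluded`` lists (cycle, reason) pairs for cycles on
    which any detector failed.
    """

    per_cycle: pd.DataFrame
    excluded: list = field(default_factory=list)
    convention: AngleConvention = field(default_factory=AngleConvention)

    def summary(self) -> pd.DataFrame:
        cols = list(EVENT_NAMES) + ["delta_SAPF_LLTD"]
        return pd.DataFrame({
            "mean": self.per_cycle[cols].mean(),
            "sd": self.per_cycle[cols].std(ddof=0),
        })


def extract_events(
    ensemble: CycleEnsemble,
    convention: AngleConvention | None = None,
    trailing_side: str = "L",
    lltd_threshold: float = 1.0,
    grad_threshold: float = 1.0,
    stance_window=(10.0, 90.0),
    max_failure_fraction: float = 0.10,
) -> GaitEvents:
    """Run all five detectors on every cycle of a segmented ensemble.

    Failed cycles are reported in ``excluded`` rather than silently dropped;
    if more than ``max_failure_fraction`` of cycles fail, aggregation raises.
    """
    convention = convention or AngleConvention()
    leading = "R" if trailing_side == "L" else "L"
    for ch in (f"ankle_{trailing_side}", f"ankle_{leading}",
               f"hip_{trailing_side}", f"knee_{trailing_side}"):
        if ch not in ensemble.cycles:
            raise InputError(f"missing channel {ch!r}")

    periods = ensemble.periods()
    n_points = len(ensemble.gc_grid)
    rows, excluded = [], []
    for c in range(ensemble.n_cycles):
        rate = n_points / periods[c]  # samples per second on this cycle's grid
        try:
            ankle_t = ensemble.cycles[f"ankle_{trailing_side}"][c]
            ankle_l = ensemble.cycles[f"ankle_{leading}"][c]
            hip = ensemble.cycles[f"hip_{trailing_side}"][c]
            knee = ensemble.cycles[f"knee_{trailing_side}"][c]
            t_sapf = detect_sapf(ankle_t, stance_window)
            t_to = detect_to(ankle_t, rate, t_sapf)
            t_lltd = detect_lltd(ankle_l, rate, t_to, lltd_threshold)
            t_shf = detect_shf(hip, rate, grad_threshold)
            t_skf = detect_skf(knee, rate, t_shf, grad_threshold)
        except DetectionError as err:
            excluded.append((c, str(err)))
            continue
        rows.append({
            "cycle": c, "t_SKF": t_skf, "t_SHF": t_shf, "t_SAPF": t_sapf,
            "t_LLTD": t_lltd, "t_TO": t_to,
            "delta_SAPF_LLTD": t_sapf - t_lltd,
        })
    if len(excluded) > max_failure_fraction * ensemble.n_cycles:
        raise DetectionError(
            f"{len(excluded)}/{ensemble.n_cycles} cycles failed event detection: "
            f"{excluded[:3]}..."
        )
    per_cycle = pd.DataFrame(rows)
    return GaitEvents(per_cycle=per_cycle, excluded=excluded, convention=convention)
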