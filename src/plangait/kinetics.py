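"""Planar forward kinematics, segmental momenta, and transition impulses.

The robot is a 7-segment planar body: two feet, two shanks, two thighs, and a
trunk whose motion is constrained to sagittal translations (all rotations
locked by a four-bar mechanism).  Horizontal trunk position comes from the
four-bar slider; vertical position from the lower-rod angle.  Segmental
linear momenta p_i = m_i * v_i are partitioned into the trailing leg (TL:
foot + shank + thigh of the push-off side), the remaining body (RB: leading
leg + trunk), and their sum, the whole-body CoM.  The step-to-step transition
runs from the minimum of vertical CoM velocity (vmin) to the second vertical
velocity peak after it (vmax); impulses are momentum differences across that
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import RobotMorphology
from .prep import DetectionError, InputError

__all__ = [
    "SegmentState",
    "SEGMENT_NAMES",
    "forward_kinematics",
    "segment_momentum",
    "partition_momentum",
    "MomentumSeries",
    "find_transition_window",
    "TransitionImpulses",
    "impulse_over_window",
    "velocity_angle_change",
    "aggregate_kinetic_energy",
    "segment_sum_kinetic_energy",
]

SEGMENT_NAMES = (
    "foot_L", "shank_L", "thigh_L", "foot_R", "shank_R", "thigh_R", "trunk",
)


@dataclass(frozen=True)
class SegmentState:
    """Mass, CoM position, and velocity of one segment at one instant."""

    name: str
    m: float
    com: tuple[float, float]
    v: tuple[float, float]

    @property
    def p(self) -> np.ndarray:
        return self.m * np.asarray(self.v, dtype=float)


def _leg_dir(theta):
    """Unit vector of a segment hanging from its proximal joint; ``theta`` is
    the flexion-positive angle from the downward vertical."""
    return np.stack([np.sin(theta), -np.cos(theta)], axis=-1)


def forward_kinematics(
    channels: dict,
    morphology: RobotMorphology,
    trunk_translation_only: bool = True,
) -> dict[str, np.ndarray]:
    """Segment CoM positions (m) from joint angles and trunk sensors.

    ``channels`` must contain hip_{L,R}, knee_{L,R}, ankle_{L,R} (rad),
    slider_x (m), and fourbar (rad); values may be scalars or equal-length
    arrays.  Returns a mapping segment name -> (..., 2) position array.

    Geometry: the hip joint sits at (slider_x, r_fourbar*sin(fourbar)); the
    thigh hangs at the hip flexion angle from vertical, the shank at
    (hip - knee), and the foot points forward at (hip - knee + ankle) from
    horizontal, so at the all-zero pose the leg is straight and the foot
    level.  Each CoM lies at its configured fraction along the segment.
    """
    required = ("hip_L", "hip_R", "knee_L", "knee_R", "ankle_L", "ankle_R",
                "slider_x", "fourbar")
    missing = [ch for ch in required if ch not in channels]
    if missing:
        raise InputError(f"missing channels for kinematics: {missing}")
    m = morphology
    sx = np.asarray(channels["slider_x"], dtype=float)
    hip_pos = np.stack(
        [sx, m.r_fourbar * np.sin(np.asarray(channels["fourbar"], dtype=float))],
        axis=-1,
    )
    com_f = m.segment_com_fractions
    out: dict[str, np.ndarray] = {"trunk": hip_pos}
    for side in ("L", "R"):
        hip = np.asarray(channels[f"hip_{side}"], dtype=float)
        knee = np.asarray(channels[f"knee_{side}"], dtype=float)
        ankle = np.asarray(channels[f"ankle_{side}"], dtype=float)
        thigh_vec = m.l_thigh * _leg_dir(hip)
        shank_vec = m.l_shank * _leg_dir(hip - knee)
        knee_pos = hip_pos + thigh_vec
        ankle_pos = knee_pos + shank_vec
        psi = hip - knee + ankle  # foot orientation from horizontal
        foot_vec = m.l_foot * np.stack([np.cos(psi), np.sin(psi)], axis=-1)
        out[f"thigh_{side}"] = hip_pos + com_f["thigh"] * thigh_vec
        out[f"shank_{side}"] = knee_pos + com_f["shank"] * shank_vec
        out[f"foot_{side}"] = ankle_pos + com_f["foot"] * foot_vec
    return out


def segment_momentum(m_i: float, v_i) -> np.ndarray:
    """p_i = m_i * v_i, componentwise and exact."""
    if m_i <= 0:
        raise InputError("segment mass must be positive")
    return m_i * np.asarray(v_i, dtype=float)


def partition_momentum(
    momenta: dict[str, np.ndarray],
    morphology: RobotMorphology,
    trailing_side: str = "L",
):
    """Sum segment momenta into (p_TL, p_RB, p_CoM).

    TL = trailing foot + shank + thigh; RB = leading leg + trunk;
    p_CoM = p_TL + p_RB holds exactly by construction.
    """
    if trailing_side not in ("L", "R"):
        raise InputError(f"trailing_side must be 'L' or 'R', got {trailing_side!r}")
    if set(momenta) != set(SEGMENT_NAMES):
        raise InputError(f"expected segments {SEGMENT_NAMES}, got {sorted(momenta)}")
    leading = "R" if trailing_side == "L" else "L"
    p_TL = sum(momenta[f"{seg}_{trailing_side}"] for seg in ("foot", "shank", "thigh"))
    p_RB = momenta["trunk"] + sum(
        momenta[f"{seg}_{leading}"] for seg in ("foot", "shank", "thigh")
    )
    return p_TL, p_RB, p_TL + p_RB


@dataclass
class MomentumSeries:
    """TL/RB/CoM momentum traces over one gait cycle.

    ``gc`` is the %GC grid; momenta are (n, 2) arrays in kg m/s; ``v_CoM`` in
    m/s.  ``masses`` maps part name (TL, RB, CoM) to its summed mass so
    aggregate kinetic energies can be formed.
    """

    gc: np.ndarray
    p_TL: np.ndarray
    p_RB: np.ndarray
    p_CoM: np.ndarray
    masses: dict[str, float]
    provenance: dict = field(default_factory=dict)

    @property
    def v_CoM(self) -> np.ndarray:
        return self.p_CoM / self.masses["CoM"]

    def part(self, name: str) -> np.ndarray:
        return {"TL": self.p_TL, "RB": self.p_RB, "CoM": self.p_CoM}[name]

    def kinetic_energy(self, name: str) -> np.ndarray:
        return aggregate_kinetic_energy(self.part(name), self.masses[name])


def find_transition_window(
    v_com_y,
    gc_grid,
    search_window=(25.0, 75.0),
    prominence_frac: float = 0.10,
    allow_single_peak: bool = False,
):
    """Locate the step-to-step transition (t_vmin, t_vmax) in %GC.

    ``t_vmin`` is the global minimum of vertical CoM velocity within the
    push-off half of the cycle (``search_window``); ``t_vmax`` is the second
    local maximum after it, peaks qualifying with prominence of at least
    ``prominence_frac`` times the post-minimum range.  The second peak marks
    the completion of the velocity redirection.
    """
    v = np.asarray(v_com_y, dtype=float)
    gc = np.asarray(gc_grid, dtype=float)
    sel = (gc >= search_window[0]) & (gc <= search_window[1])
    idx_sel = np.nonzero(sel)[0]
    if len(idx_sel) < 5:
        raise InputError("search window too narrow")
    i_min = idx_sel[int(np.argmin(v[idx_sel]))]
    post = v[i_min: idx_sel[-1] + 1]
    if np.ptp(post) == 0:
        raise DetectionError("vertical CoM velocity is flat after its minimum")
    prominence = prominence_frac * np.ptp(post)
    peaks, _ = find_peaks(post, prominence=prominence)
    if len(peaks) >= 2:
        i_max = i_min + int(peaks[1])
    elif len(peaks) == 1 and allow_single_peak:
        i_max = i_min + int(peaks[0])
    else:
        raise DetectionError(
            f"found {len(peaks)} vertical-velocity peak(s) after vmin; need 2"
        )
    return float(gc[i_min]), float(gc[i_max])


@dataclass
class TransitionImpulses:
    """Momentum changes over the step-to-step transition for one cycle.

    ``delta[part]`` is the (dx, dy) impulse vector; ``delta_mag[part]`` the
    change of the momentum-vector magnitude |p(vmax)| - |p(vmin)|;
    ``at_lltd`` the intermediate momentum values at leading-leg touch-down
    (three-timepoint summaries).  Angles in degrees.
    """

    t_vmin: float
    t_vmax: float
    delta: dict[str, np.ndarray]
    delta_mag: dict[str, float]
    at_lltd: dict[str, np.ndarray] = field(default_factory=dict)
    velocity_angle_change_deg: float = float("nan")


def _interp_vec(gc, arr, t):
    return np.array([np.interp(t, gc, arr[:, 0]), np.interp(t, gc, arr[:, 1])])


def impulse_over_window(
    series: MomentumSeries,
    window: tuple[float, float],
    t_lltd: float | None = None,
) -> TransitionImpulses:
    """Evaluate Δp (componentwise and in vector magnitude) for TL, RB, CoM
    between the window endpoints, plus the intermediate values at LLTD."""
    t0, t1 = window
    gc = series.gc
    if not (gc[0] <= t0 <= gc[-1] and gc[0] <= t1 <= gc[-1]):
        raise ValueError(f"window {window} outside the %GC grid")
    delta, delta_mag, at_lltd = {}, {}, {}
    for part in ("TL", "RB", "CoM"):
        arr = series.part(part)
        p0, p1 = _interp_vec(gc, arr, t0), _interp_vec(gc, arr, t1)
        delta[part] = p1 - p0
        delta_mag[part] = float(np.linalg.norm(p1) - np.linalg.norm(p0))
        if t_lltd is not None:
            at_lltd[part] = _interp_vec(gc, arr, t_lltd)
    v0 = _interp_vec(gc, series.v_CoM, t0)
    v1 = _interp_vec(gc, series.v_CoM, t1)
    angle = velocity_angle_change(v0, v1)
    return TransitionImpulses(
        t_vmin=t0, t_vmax=t1, delta=delta, delta_mag=delta_mag,
        at_lltd=at_lltd, velocity_angle_change_deg=angle,
    )


def velocity_angle_change(v0, v1) -> float:
    """Signed angle (deg) from v0 to v1, positive for upward redirection."""
    v0 = np.asarray(v0, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    if np.linalg.norm(v0) == 0 or np.linalg.norm(v1) == 0:
        raise ValueError("velocity vectors must be nonzero")
    cross = v0[0] * v1[1] - v0[1] * v1[0]
    dot = float(np.dot(v0, v1))
    return float(np.degrees(np.arctan2(cross, dot)))


def aggregate_kinetic_energy(p, m_part: float):
    """|p|^2 / (2 m): kinetic energy of a body part treated as a point mass
    carrying its aggregate momentum (tracks the part's velocity vector)."""
    p = np.asarray(p, dtype=float)
    return (p ** 2).sum(axis=-1) / (2.0 * m_part)


def segment_sum_kinetic_energy(momenta: dict[str, np.ndarray],
                               masses: dict[str, float]):
    """Sum of per-segment (1/2) m v^2 - the translational energy including
    within-part relative motion."""
    return sum(
        (np.asarray(p, dtype=float) ** 2).sum(axis=-1) / (2.0 * masses[name])
        for name, p in momenta.items()
    )
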