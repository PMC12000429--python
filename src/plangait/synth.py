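"""Synthetic robot-like gait logs with known ground-truth event schedules.

The generator emulates the statistical structure of planar-biped treadmill
logs: 1 Hz gait cycles, ~600 Hz control-loop-synchronized (jittered)
sampling, encoder quantization, condition-dependent event timing (active vs
passive knee-flexion initiation), a stance dorsiflexion ramp with a ~-22 deg
swing ankle plateau, and ~120 steady cycles per condition.

Curves are piecewise smooth (cosine/Hermite-blended) segments parameterized
by the CPG table quantities and the per-cycle event schedule; the published
controller differential equations and reference trajectories are not
available, and the analysis pipeline consumes kinematic shapes, not
controller internals.  Ground-truth semantics match the detector
definitions: scheduled t_SHF/t_SKF are the instants the (noiseless) joint
gradient crosses +1 rad/s, scheduled t_LLTD is the last instant the leading
ankle gradient exceeds 1 rad/s (the end of the touch-down transient), and
t_SAPF / t_TO are the ankle reversal extrema.

The trunk channels (four-bar slider and lower-rod angle) are solved so that
the whole-body CoM velocity follows a per-condition hodograph profile with
one vertical-velocity minimum followed by two similar-height peaks per step;
the profiles are anchored to the conditions' published transition values
(horizontal 0.41 m/s at the second peak, vertical 0.14/0.13 m/s, CoM
impulses of 0.12/0.79 vs 0.16/0.66 kg m/s between conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config import (
    DEG,
    ConfigurationError,
    ControlMode,
    ControlParams,
    RobotMorphology,
    params_for_mode,
    validate_morphology,
)
from .kinetics import forward_kinematics
from .log import TimeSeriesLog, UniformLog

__all__ = [
    "EventSchedule",
    "NoiseModel",
    "SyntheticScenario",
    "CONDITION_DEFAULTS",
    "cpg_reference_trajectory",
    "schedule_ground_truth",
    "synthesize_joint_angles",
    "apply_sensor_model",
    "simulate",
]

EVENT_ORDER = ("t_SKF", "t_SHF", "t_SAPF", "t_LLTD", "t_TO")


@dataclass(frozen=True)
class ConditionProfile:
    """Event-timing means (%GC) and CoM-velocity hodograph of one condition."""

    events: dict[str, float]
    # Hodograph keypoints on the half-cycle phase u = (%GC mod 50); the CoM
    # profile repeats every step (each leg's transition once per cycle).
    hodograph_u: tuple
    hodograph_vy: tuple
    hodograph_vx: tuple
    cot_target: float


CONDITION_DEFAULTS: dict[ControlMode, ConditionProfile] = {
    ControlMode.AKFI: ConditionProfile(
        events={"t_SKF": 39.00, "t_SHF": 40.50, "t_SAPF": 46.25,
                "t_LLTD": 47.87, "t_TO": 62.00},
        hodograph_u=(0.0, 7.0, 11.5, 16.0, 25.0, 35.0, 42.0, 47.0),
        hodograph_vy=(-0.02, 0.132, 0.085, 0.140, 0.06, -0.02, -0.12, -0.236),
        hodograph_vx=(0.39, 0.40, 0.41, 0.41, 0.45, 0.46, 0.42, 0.353),
        cot_target=0.56,
    ),
    ControlMode.PKFI: ConditionProfile(
        events={"t_SKF": 43.67, "t_SHF": 44.50, "t_SAPF": 48.77,
                "t_LLTD": 46.89, "t_TO": 64.00},
        hodograph_u=(0.0, 8.5, 13.0, 18.0, 26.0, 36.0, 41.5, 46.5),
        hodograph_vy=(-0.02, 0.122, 0.075, 0.130, 0.06, -0.02, -0.10, -0.184),
        hodograph_vx=(0.38, 0.395, 0.40, 0.41, 0.45, 0.46, 0.41, 0.334),
        cot_target=0.52,
    ),
}
# Timing independence from the zero-torque onset: the 40 %GC variant shares
# the passive condition's schedule and energetics.
CONDITION_DEFAULTS[ControlMode.PKFI40] = CONDITION_DEFAULTS[ControlMode.PKFI]


# ---------------------------------------------------------------------------
# curve-shape constants (radians / seconds); configurable only in source on
# purpose: they define the study conditions, not tuning knobs.
A_PLATEAU = -22.0 * DEG      # swing ankle plateau
A_MAX = -6.0 * DEG           # stance dorsiflexion maximum (at SAPF)
A_PRE_TO = -17.0 * DEG       # ankle angle entering the fast pre-TO drop
A_UNDER = 0.4 * DEG          # undershoot below the plateau at TO
TD_V0 = 2.0                  # rad/s, ankle speed during the contact transient
TD_HOLD = 0.010              # s, constant-speed part of the transient
TD_DECAY = 0.015             # s, linear decay of the transient speed
TD_V1 = 0.5                  # rad/s, speed at the transient's end
SAPF_VCAP = 0.4              # rad/s, |slope| at the edges of the SAPF cap
W_SAPF = 0.015               # s, halfwidth of the parabolic SAPF cap
TO_FAST = 0.025              # s, duration of the fast pre-TO plantarflexion
TO_VCAP = 0.4                # rad/s, |slope| at the edges of the TO cap
W_TO = 0.015                 # s, halfwidth of the parabolic TO cap
REV_ACC = 50.0               # rad/s^2, hip/knee reversal acceleration ramp
REV_LEAD = 1.0 / REV_ACC     # s between reversal onset and the 1 rad/s crossing
KNEE_PEAK_FRAC = 0.71        # peak knee flexion as a fraction of the cycle
HIP_TD_DEG = 30.0            # hip angle at touch-down (deg)

# Offset between foot contact and the scheduled LLTD (the transient's last
# 1 rad/s gradient crossing): TD_HOLD + TD_DECAY*(TD_V0-1)/(TD_V0-TD_V1).
CONTACT_TO_LLTD = TD_HOLD + TD_DECAY * (TD_V0 - 1.0) / (TD_V0 - TD_V1)


@dataclass
class EventSchedule:
    """Per-cycle ground-truth event times in %GC plus cycle periods (s).

    ``events[name]`` are arrays of length n_cycles; ordering
    SKF <= SHF <= SAPF < TO is enforced per cycle.  ``seed`` reproduces the
    schedule bit-identically.
    """

    mode: ControlMode
    events: dict[str, np.ndarray]
    periods: np.ndarray
    seed: int | None = None
    jitter_sd: float = 0.3

    def __post_init__(self):
        self.events = {k: np.asarray(v, dtype=float) for k, v in self.events.items()}
        self.periods = np.asarray(self.periods, dtype=float)
        n = len(self.periods)
        for name in EVENT_ORDER:
            if name not in self.events or len(self.events[name]) != n:
                raise ConfigurationError(f"schedule missing or misaligned event {name}")
            vals = self.events[name]
            if np.any((vals < 0) | (vals >= 100)):
                raise ConfigurationError(f"{name} must lie in [0, 100)")
        e = self.events
        ok = (
            (e["t_SKF"] <= e["t_SHF"])
            & (e["t_SHF"] <= e["t_SAPF"])
            & (e["t_SAPF"] < e["t_TO"])
        )
        if not np.all(ok):
            raise ConfigurationError("event ordering SKF <= SHF <= SAPF < TO violated")

    @property
    def n_cycles(self) -> int:
        return len(self.periods)


@dataclass(frozen=True)
class NoiseModel:
    """Sensor model: jittered ~600 Hz sampling, encoder quantization, noise.

    ``sampling_jitter`` is the fractional perturbation of the nominal sample
    spacing (uniform in +-jitter).  Encoder resolutions are counts per
    revolution per channel family; the quantization step is 2*pi/counts.
    ``seed`` controls only the sensor-model randomness.
    """

    sampling_rate_nominal: float = 600.0
    sampling_jitter: float = 0.2
    encoder_counts: dict = field(default_factory=lambda: {
        "hip": 5000, "knee": 5000, "ankle": 4096, "fourbar": 4096,
    })
    angle_noise_sd: float = 2e-4    # rad
    slider_noise_sd: float = 2e-4   # m
    current_noise_sd: float = 5e-3  # A
    seed: int | None = None

    def counts_for(self, channel: str):
        for prefix, counts in self.encoder_counts.items():
            if channel.startswith(prefix):
                return counts
        return None


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete description of one synthetic experiment."""

    control: ControlParams = field(default_factory=ControlParams)
    morphology: RobotMorphology = field(default_factory=validate_morphology)
    n_cycles: int = 120
    noise: NoiseModel = field(default_factory=NoiseModel)
    mean_forward_speed: float = 0.44
    event_jitter_sd: float = 0.3   # %GC, per-cycle event timing jitter
    period_jitter_sd: float = 0.002  # s
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 2:
            raise ConfigurationError("n_cycles must be >= 2")


def cpg_reference_trajectory(params: ControlParams, phase_grid, side: str = "L"):
    """Commanded hip and knee angles (rad) of the phase-oscillator CPG.

    The hip oscillates within offset +- amplitude with a steady segment of
    duration ``phi_hip`` at the end of swing; the knee flexes by its
    amplitude above its offset starting at phase ``F_knee``.  The right-side
    curve is the left curve shifted by ``phase_shift_lr``.
    """
    phi = np.asarray(phase_grid, dtype=float)
    if np.any((phi < 0) | (phi >= 1)):
        raise ValueError("phase grid must lie in [0, 1)")
    if side == "R":
        phi = (phi + params.phase_shift_lr) % 1.0
    amp_k = params.theta_kneeAmplitude * DEG
    off_k = params.theta_kneeOffset * DEG
    amp_h = params.theta_hipAmplitude * DEG
    off_h = params.theta_hipOffset * DEG

    knee = np.full_like(phi, off_k)
    flex = phi >= params.F_knee
    s = (phi[flex] - params.F_knee) / (1.0 - params.F_knee)
    knee[flex] = off_k + amp_k * np.sin(np.pi * s) ** 2

    active = 1.0 - params.phi_hip
    hip = np.full_like(phi, off_h + amp_h)
    osc = phi < active
    hip[osc] = off_h + amp_h * np.cos(2 * np.pi * phi[osc] / active)
    return hip, knee


def schedule_ground_truth(
    control: ControlParams,
    n_cycles: int,
    seed: int | None = None,
    jitter_sd: float = 0.3,
    period: float | None = None,
    period_jitter_sd: float = 0.0,
    means: dict[str, float] | None = None,
) -> EventSchedule:
    """Draw a per-cycle event schedule: condition means plus small jitter.

    Event ordering is enforced per cycle by sorting the SKF/SHF/SAPF triple
    (jitter SDs are well below the event gaps, so sorting is a no-op in all
    but pathological draws).
    """
    if n_cycles < 2:
        raise ConfigurationError("n_cycles must be >= 2")
    means = dict(means or CONDITION_DEFAULTS[control.mode].events)
    if not (means["t_SKF"] <= means["t_SHF"] <= means["t_SAPF"] < means["t_TO"]):
        raise ConfigurationError(f"event means violate ordering: {means}")
    rng = np.random.default_rng(seed)
    events = {
        name: means[name] + jitter_sd * rng.standard_normal(n_cycles)
        for name in EVENT_ORDER
    }
    tri = np.sort(np.stack([events["t_SKF"], events["t_SHF"], events["t_SAPF"]]), axis=0)
    events["t_SKF"], events["t_SHF"], events["t_SAPF"] = tri
    events["t_TO"] = np.maximum(events["t_TO"], events["t_SAPF"] + 5.0)
    period = period if period is not None else control.period
    periods = period + period_jitter_sd * rng.standard_normal(n_cycles)
    return EventSchedule(mode=control.mode, events=events, periods=periods,
                         seed=seed, jitter_sd=jitter_sd)


# -- piecewise curve primitives ---------------------------------------------

def _hermite(tau, a, b, p0, v0, p1, v1):
    s = (tau - a) / (b - a)
    L = b - a
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * p0 + h10 * L * v0 + h01 * p1 + h11 * L * v1


def _cosine(tau, a, b, p0, p1):
    s = (tau - a) / (b - a)
    return p0 + (p1 - p0) * 0.5 * (1.0 - np.cos(np.pi * s))


def _ankle_cycle(tau, T, t_sapf, t_to):
    """Ankle angle (rad) over one cycle; tau in [0, T) seconds.

    The SAPF maximum and TO minimum are parabolic caps with equal edge-slope
    magnitudes, so they are locally even-symmetric and the zero-phase filter
    does not displace the extremum.
    """
    th_c = A_PLATEAU + TD_V0 * TD_HOLD + 0.5 * (TD_V0 + TD_V1) * TD_DECAY
    sapf_edge = A_MAX - SAPF_VCAP * W_SAPF / 2.0
    a_to_min = A_PLATEAU - A_UNDER
    to_edge = a_to_min + TO_VCAP * W_TO / 2.0
    rec_gain = A_PLATEAU - to_edge          # > 0, remaining rise to plateau
    t_rec = 2.0 * rec_gain / TO_VCAP        # quadratic deceleration to the plateau

    t1 = TD_HOLD
    t2 = TD_HOLD + TD_DECAY
    t3a, t3b = t_sapf - W_SAPF, t_sapf + W_SAPF
    t4 = t_to - TO_FAST
    t5a, t5b = t_to - W_TO, t_to + W_TO
    t6 = t5b + t_rec
    out = np.empty_like(tau)

    m = tau < t1
    out[m] = A_PLATEAU + TD_V0 * tau[m]
    m = (tau >= t1) & (tau < t2)
    u = tau[m] - t1
    out[m] = (A_PLATEAU + TD_V0 * t1 + TD_V0 * u
              - (TD_V0 - TD_V1) * u**2 / (2 * TD_DECAY))
    m = (tau >= t2) & (tau < t3a)
    out[m] = _hermite(tau[m], t2, t3a, th_c, TD_V1, sapf_edge, SAPF_VCAP)
    m = (tau >= t3a) & (tau < t3b)
    out[m] = A_MAX - SAPF_VCAP * (tau[m] - t_sapf) ** 2 / (2 * W_SAPF)
    m = (tau >= t3b) & (tau < t4)
    out[m] = _hermite(tau[m], t3b, t4, sapf_edge, -SAPF_VCAP, A_PRE_TO, 0.0)
    m = (tau >= t4) & (tau < t5a)
    out[m] = _hermite(tau[m], t4, t5a, A_PRE_TO, 0.0, to_edge, -TO_VCAP)
    m = (tau >= t5a) & (tau < t5b)
    out[m] = a_to_min + TO_VCAP * (tau[m] - t_to) ** 2 / (2 * W_TO)
    m = (tau >= t5b) & (tau < t6)
    u = tau[m] - t5b
    out[m] = to_edge + TO_VCAP * u - TO_VCAP**2 * u**2 / (4 * rec_gain)
    out[tau >= t6] = A_PLATEAU
    return out


def _ramp_decay(tau, t_start, t_end, gain):
    """Reversal profile: linear acceleration ramp at REV_ACC into a cosine
    velocity decay reaching zero at ``t_end``; total angle change ``gain``.
    The 1 rad/s gradient crossing falls exactly REV_LEAD after ``t_start``."""
    T_sw = t_end - t_start
    v_pk = 2.0 * gain / T_sw
    tau_b = min(v_pk / REV_ACC, T_sw)
    S = T_sw - tau_b
    u = np.clip(tau - t_start, 0.0, T_sw)
    ramp = u < tau_b
    out = np.empty_like(u)
    out[ramp] = 0.5 * REV_ACC * u[ramp]**2
    u2 = u[~ramp] - tau_b
    out[~ramp] = (0.5 * REV_ACC * tau_b**2
                  + 0.5 * v_pk * (u2 + S / np.pi * np.sin(np.pi * u2 / S)))
    return out


def _hip_cycle(tau, T, t_shf, phi_hip, amp, off):
    th_td = HIP_TD_DEG * DEG
    th_min = (off - amp) * DEG
    t_r = t_shf - REV_LEAD
    t_hold = (1.0 - phi_hip) * T
    out = np.empty_like(tau)
    m = tau < t_r
    out[m] = _cosine(tau[m], 0.0, t_r, th_td, th_min)
    m = (tau >= t_r) & (tau < t_hold)
    out[m] = th_min + _ramp_decay(tau[m], t_r, t_hold, th_td - th_min)
    out[tau >= t_hold] = th_td
    return out


def _knee_cycle(tau, T, t_skf, phi_hip, amp, off):
    """Knee angle over one cycle: constant stance value, a cosine-blend
    flexion (sinusoidal angular velocity) peaking at a fixed cycle fraction,
    then a cosine extension back to the stance value before the hold.

    Peak knee flexion sits at the same cycle fraction in both conditions, so
    a later (passive) flexion onset flexes faster.  The flexion is placed so
    its angular velocity crosses +1 rad/s exactly at ``t_skf``.
    """
    th_st = off * DEG
    gain = amp * DEG
    t_pk = KNEE_PEAK_FRAC * T
    t_hold = (1.0 - phi_hip) * T
    # sinusoidal velocity v(s) = v_pk*sin(pi*s) crosses 1 rad/s at
    # lead = (T_fl/pi)*asin(1/v_pk) after flexion start; solve by iteration
    lead = 0.0
    for _ in range(4):
        T_fl = t_pk - (t_skf - lead)
        v_pk = np.pi * gain / (2.0 * T_fl)
        lead = (T_fl / np.pi) * math.asin(min(1.0, 1.0 / v_pk))
    t_start = t_skf - lead
    out = np.full_like(tau, th_st)
    m = (tau >= t_start) & (tau < t_pk)
    out[m] = _cosine(tau[m], t_start, t_pk, th_st, th_st + gain)
    m = (tau >= t_pk) & (tau < t_hold)
    out[m] = _cosine(tau[m], t_pk, t_hold, th_st + gain, th_st)
    out[tau >= t_hold] = th_st
    return out


def _leg_channels(t, td_times, periods, events_s, control: ControlParams):
    """Evaluate hip/knee/ankle (rad) for one leg at global times ``t``.

    ``events_s`` maps event name -> per-cycle time offsets in seconds.
    Samples before the first cycle get the hold/plateau pose.
    """
    hip = np.full_like(t, HIP_TD_DEG * DEG)
    knee = np.full_like(t, control.theta_kneeOffset * DEG)
    ankle = np.full_like(t, A_PLATEAU)
    idx = np.searchsorted(td_times, t, side="right") - 1
    for c in range(len(td_times)):
        m = idx == c
        if not np.any(m):
            continue
        T = periods[c]
        tau = np.clip(t[m] - td_times[c], 0.0, T * (1 - 1e-12))
        ankle[m] = _ankle_cycle(tau, T, events_s["t_SAPF"][c], events_s["t_TO"][c])
        hip[m] = _hip_cycle(tau, T, events_s["t_SHF"][c], control.phi_hip,
                            control.theta_hipAmplitude, control.theta_hipOffset)
        knee[m] = _knee_cycle(tau, T, events_s["t_SKF"][c], control.phi_hip,
                              control.theta_kneeAmplitude, control.theta_kneeOffset)
    return hip, knee, ankle


def _bump(tau, a, b):
    """Raised-cosine bump, 0 outside [a, b], unit peak."""
    out = np.zeros_like(tau)
    m = (tau >= a) & (tau < b)
    out[m] = np.sin(np.pi * (tau[m] - a) / (b - a)) ** 2
    return out


class _PeriodicCosineProfile:
    """Periodic (period 50 %GC) interpolant with cosine blends between
    knots: C^1, with extrema exactly at the knots (no overshoot)."""

    def __init__(self, knots, values, period: float = 50.0):
        self.u = np.asarray(knots, dtype=float)
        self.v = np.asarray(values, dtype=float)
        self.period = period
        if np.any(np.diff(self.u) <= 0) or self.u[-1] >= period:
            raise ConfigurationError("profile knots must be increasing within the period")
        # mean of a cosine blend over a segment is the midpoint value
        widths = np.diff(np.append(self.u, self.u[0] + period))
        mids = 0.5 * (self.v + np.roll(self.v, -1))
        self.mean = float(np.sum(widths * mids) / period)

    def __call__(self, u):
        u = np.asarray(u, dtype=float) % self.period
        # segment index: last knot <= u (wrapping below the first knot)
        idx = np.searchsorted(self.u, u, side="right") - 1
        wrap = idx < 0
        idx = np.where(wrap, len(self.u) - 1, idx)
        u_adj = np.where(wrap, u + self.period, u)
        u0 = self.u[idx]
        u1 = np.append(self.u, self.u[0] + self.period)[idx + 1]
        s = (u_adj - u0) / (u1 - u0)
        v0, v1 = self.v[idx], np.roll(self.v, -1)[idx]
        return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))


def _hodograph_profiles(profile: ConditionProfile, mean_speed: float):
    """CoM-velocity target profiles, adjusted to zero vertical mean and
    ``mean_speed`` horizontal mean."""
    spl_y = _PeriodicCosineProfile(profile.hodograph_u, profile.hodograph_vy)
    spl_x = _PeriodicCosineProfile(profile.hodograph_u, profile.hodograph_vx)
    off_y = spl_y.mean
    off_x = mean_speed - spl_x.mean
    return spl_x, spl_y, off_x, off_y


def _transition_truth(profile: ConditionProfile, mean_speed: float):
    """(t_vmin, t_vmax) in %GC of the condition's CoM hodograph, computed
    from the dense profile with the same rule the analysis uses."""
    from .kinetics import find_transition_window

    spl_x, spl_y, _, off_y = _hodograph_profiles(profile, mean_speed)
    gc = np.linspace(0.0, 100.0, 4001)
    vy = spl_y(gc % 50.0) - off_y
    return find_transition_window(vy, gc)


def synthesize_joint_angles(
    schedule: EventSchedule,
    control: ControlParams,
    morphology: RobotMorphology,
    rate: float = 1000.0,
    mean_forward_speed: float = 0.44,
    lead_in: float = 0.3,
    schedule_R: EventSchedule | None = None,
) -> UniformLog:
    """Render a noiseless uniform log from an event schedule.

    Returns a :class:`UniformLog` whose metadata carries the ground truth:
    cycle boundaries (left touch-downs, seconds), the per-cycle schedule,
    and the transition-window targets.  The trunk channels are solved so the
    whole-body CoM velocity matches the condition's hodograph profile given
    the leg kinematics.
    """
    if rate <= 0:
        raise ConfigurationError("rate must be positive")
    profile = CONDITION_DEFAULTS[schedule.mode]
    n = schedule.n_cycles
    td_L = lead_in + np.concatenate([[0.0], np.cumsum(schedule.periods)])[:n]
    duration = lead_in + float(np.sum(schedule.periods)) + lead_in
    t = np.arange(int(round(duration * rate))) / rate

    ev_L = {name: schedule.events[name] / 100.0 * schedule.periods
            for name in EVENT_ORDER}

    # Leading (right) leg: same condition statistics, independent jitter,
    # placed so its touch-down transient's last 1 rad/s crossing lands on the
    # scheduled LLTD of each left cycle.
    if schedule_R is None:
        seed_r = None if schedule.seed is None else (int(schedule.seed) + 1) % 2**31
        schedule_R = schedule_ground_truth(
            params_for_mode(schedule.mode), n, seed=seed_r,
            jitter_sd=schedule.jitter_sd, period=float(np.mean(schedule.periods)),
        )
    lltd_abs = td_L + schedule.events["t_LLTD"] / 100.0 * schedule.periods
    td_R = lltd_abs - CONTACT_TO_LLTD
    td_R = np.concatenate([[2 * td_R[0] - td_R[1]], td_R])  # cover the lead-in
    periods_R = np.diff(np.append(td_R, td_R[-1] + schedule.periods[-1]))
    ev_R = {name: np.concatenate([[schedule_R.events[name][0]],
                                  schedule_R.events[name]]) / 100.0 * periods_R
            for name in EVENT_ORDER}

    hip_L, knee_L, ankle_L = _leg_channels(t, td_L, schedule.periods, ev_L, control)
    hip_R, knee_R, ankle_R = _leg_channels(t, td_R, periods_R, ev_R, control)

    channels = {
        "hip_L": hip_L, "hip_R": hip_R, "knee_L": knee_L, "knee_R": knee_R,
        "ankle_L": ankle_L, "ankle_R": ankle_R,
    }

    # --- trunk channels from the CoM-velocity target -----------------------
    rel = forward_kinematics(
        {**channels, "slider_x": np.zeros_like(t), "fourbar": np.zeros_like(t)},
        morphology,
    )
    M = morphology.total_mass
    leg_mom = np.zeros((len(t), 2))
    for name, pos in rel.items():
        if name == "trunk":
            continue
        leg_mom += morphology.segment_mass(name) * np.gradient(pos, axis=0) * rate

    spl_x, spl_y, off_x, off_y = _hodograph_profiles(profile, mean_forward_speed)
    idx = np.clip(np.searchsorted(td_L, t, side="right") - 1, 0, n - 1)
    phi = (t - td_L[idx]) / schedule.periods[idx] * 100.0
    u = phi % 50.0
    v_target = np.stack([spl_x(u) + off_x, spl_y(u) - off_y], axis=-1)

    v_trunk = v_target - leg_mom / M
    slider_x = cumulative_trapezoid(v_trunk[:, 0], t, initial=0.0)
    y = cumulative_trapezoid(v_trunk[:, 1], t, initial=0.0)
    y = y - np.mean(y)
    arg = np.clip(y / morphology.r_fourbar, -0.99, 0.99)
    channels["slider_x"] = slider_x
    channels["fourbar"] = np.arcsin(arg)

    # --- motor currents -----------------------------------------------------
    knee_act = 0.7 if schedule.mode is ControlMode.AKFI else 0.25
    power = {k: np.zeros_like(t) for k in ("I_hip_L", "I_hip_R", "I_knee_L", "I_knee_R")}
    for side, td, periods, ev in (("L", td_L, schedule.periods, ev_L),
                                  ("R", td_R, periods_R, ev_R)):
        idx_s = np.searchsorted(td, t, side="right") - 1
        for c in range(len(td)):
            m = idx_s == c
            if not np.any(m):
                continue
            tau = t[m] - td[c]
            T = periods[c]
            power[f"I_hip_{side}"][m] += (
                _bump(tau, ev["t_SHF"][c], (1 - control.phi_hip) * T)
                + 0.5 * _bump(tau, 0.05 * T, 0.35 * T)
            )
            power[f"I_knee_{side}"][m] += knee_act * _bump(
                tau, ev["t_SKF"][c], KNEE_PEAK_FRAC * T
            )
    total_unit = np.sum(list(power.values()), axis=0)
    E_target = profile.cot_target * M * morphology.g * mean_forward_speed
    scale = E_target / float(np.mean(total_unit))
    for name, p in power.items():
        channels[name] = scale * p / morphology.U_supply

    t_vmin, t_vmax = _transition_truth(profile, mean_forward_speed)
    truth = {
        "mode": schedule.mode.value,
        "schedule_seed": schedule.seed,
        "boundaries_s": td_L.tolist() + [float(td_L[-1] + schedule.periods[-1])],
        "periods_s": schedule.periods.tolist(),
        "events_gc": {k: v.tolist() for k, v in schedule.events.items()},
        "t_vmin_gc": t_vmin,
        "t_vmax_gc": t_vmax,
        "mean_forward_speed": mean_forward_speed,
        "cot_target": profile.cot_target,
    }
    return UniformLog(
        rate=rate, t0=0.0, channels=channels,
        metadata={"condition": schedule.mode.value, "truth": truth,
                  "sampling": f"uniform {rate:g} Hz (noiseless synthetic)"},
    )


def apply_sensor_model(log: UniformLog, noise: NoiseModel) -> TimeSeriesLog:
    """Resample a noiseless uniform log through the sensor model.

    Timestamps are re-drawn with jittered spacing around the nominal rate
    (control-loop-synchronized sampling), angle channels are quantized to
    their encoder resolution after additive noise, and the ground-truth
    metadata passes through untouched.
    """
    rng = np.random.default_rng(noise.seed)
    t_in = log.times
    dt_nom = 1.0 / noise.sampling_rate_nominal
    n_est = int((t_in[-1] - t_in[0]) / dt_nom) + 2
    for _ in range(10):
        dt = dt_nom * (1.0 + noise.sampling_jitter
                       * rng.uniform(-1.0, 1.0, size=n_est))
        if np.all(dt > 0):
            break
    else:
        raise RuntimeError("sampling jitter produced non-increasing timestamps")
    stamps = t_in[0] + np.concatenate([[0.0], np.cumsum(dt)])
    stamps = stamps[stamps <= t_in[-1]]

    channels = {}
    for name, series in log.channels.items():
        vals = np.interp(stamps, t_in, series)
        if name.startswith("I_"):
            vals = vals + noise.current_noise_sd * rng.standard_normal(len(vals))
        elif name == "slider_x":
            vals = vals + noise.slider_noise_sd * rng.standard_normal(len(vals))
        else:
            vals = vals + noise.angle_noise_sd * rng.standard_normal(len(vals))
            counts = noise.counts_for(name)
            if counts is not None and np.isfinite(counts):
                q = 2.0 * np.pi / counts
                vals = np.round(vals / q) * q
        channels[name] = vals
    metadata = dict(log.metadata)
    metadata["sampling"] = (
        f"control-loop jittered, nominal {noise.sampling_rate_nominal:g} Hz"
    )
    metadata["noise_seed"] = noise.seed
    return TimeSeriesLog(stamps, channels, metadata)


def simulate(scenario: SyntheticScenario, rate: float = 1000.0,
             noiseless: bool = False):
    """Generate a full synthetic experiment from a scenario.

    Returns ``(log, truth)`` where ``log`` is a :class:`TimeSeriesLog`
    (or the noiseless :class:`UniformLog` when ``noiseless``) and ``truth``
    the ground-truth dictionary.  All randomness derives from
    ``scenario.seed``.
    """
    ss = np.random.SeedSequence(scenario.seed)
    seed_sched, seed_noise = [int(s.generate_state(1)[0] % 2**31)
                              for s in ss.spawn(2)]
    # generate one extra cycle so n_cycles full cycles have a closing boundary
    schedule = schedule_ground_truth(
        scenario.control, scenario.n_cycles + 1, seed=seed_sched,
        jitter_sd=scenario.event_jitter_sd,
        period_jitter_sd=scenario.period_jitter_sd,
    )
    uniform = synthesize_joint_angles(
        schedule, scenario.control, scenario.morphology, rate=rate,
        mean_forward_speed=scenario.mean_forward_speed,
    )
    truth = uniform.metadata["truth"]
    truth["scenario_seed"] = scenario.seed
    if noiseless:
        return uniform, truth
    noise = scenario.noise if scenario.noise.seed is not None else replace(
        scenario.noise, seed=seed_noise
    )
    log = apply_sensor_model(uniform, noise)
    return log, truth
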