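"""Spring-tendon joint power, motor electrical power, and cost of transport.

The ankle is driven passively by two linear spring-tendons over constant-
radius pulleys: SOL (monoarticular, ankle only) and GAS (biarticular,
ankle-knee).  Tendon extensions are measured relative to the slack
calibration pose (ankle -22 deg, knee 0 deg, slack lengths 0), so in the
power equations the angles alpha mean (measured angle - calibration angle).

Ankle joint power (dorsiflexion-positive angles, extension-relative):

    P_A = w_A * [k_SOL r_SOL (a_A r_SOL - l_SOL,slack)
                 + k_GAS r_GAS ((a_A - a_K) r_GAS - l_GAS,slack)]   if a_A >= a_K
    P_A = w_A * k_SOL r_SOL (a_A r_SOL - l_SOL,slack)               otherwise

GAS contribution to knee power:

    P_K,GAS = w_K * k_GAS r_GAS ((a_A - a_K) r_GAS - l_GAS,slack)

Electrical joint power is P = I_cal * U_supply per motor channel; the net
positive energy rate E_en sums the four channels, subtracts driver idle
power, clips negatives to zero (in that order), and averages over the cycle.
COT = E_en / (m g v); the relative COT expresses it as a percentage of a
same-mass natural runner's COT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, RobotMorphology

__all__ = [
    "JointState",
    "ankle_power",
    "knee_gas_power",
    "motor_power",
    "net_positive_energy",
    "cost_of_transport",
    "relative_cot",
    "EnergySummary",
    "COT_NATURAL_RUNNER",
]

# Natural runner's cost of transport at the robot's body mass (2.1 kg),
# taken as an input constant; the allometric formula behind it is out of
# scope here.
COT_NATURAL_RUNNER = 1.36


@dataclass(frozen=True)
class JointState:
    """Ankle/knee angles (rad) and angular velocities (rad/s).

    Angles are in the measurement convention (ankle dorsiflexion positive
    with swing plateau near -22 deg, knee flexion positive); the conversion
    to slack-relative values happens inside the power functions.
    """

    alpha_A: float
    alpha_K: float
    omega_A: float
    omega_K: float


def _relative_angles(state: JointState, m: RobotMorphology):
    return state.alpha_A - m.alpha_A_slack, state.alpha_K - m.alpha_K_slack


def ankle_power(state: JointState, morphology: RobotMorphology,
                clamp_slack: bool = False):
    """Ankle joint power P_A in W delivered by the SOL and GAS tendons.

    With ``clamp_slack`` set, each bracketed tendon force is floored at zero
    (a physical tendon cannot push); the default follows the unclamped
    piecewise form, under which P_A is the exact time derivative of the SOL
    elastic energy whenever the knee stays at its calibration angle.
    Accepts scalars or aligned arrays in ``state``.
    """
    m = morphology
    a_A, a_K = _relative_angles(state, m)
    a_A, a_K = np.asarray(a_A, dtype=float), np.asarray(a_K, dtype=float)
    f_sol = m.k_SOL * (a_A * m.r_SOL - m.l_SOL_slack)
    f_gas = m.k_GAS * ((a_A - a_K) * m.r_GAS - m.l_GAS_slack)
    if clamp_slack:
        f_sol = np.maximum(f_sol, 0.0)
        f_gas = np.maximum(f_gas, 0.0)
    engaged = a_A >= a_K
    torque = m.r_SOL * f_sol + np.where(engaged, m.r_GAS * f_gas, 0.0)
    return np.asarray(state.omega_A, dtype=float) * torque


def knee_gas_power(state: JointState, morphology: RobotMorphology,
                   clamp_slack: bool = False):
    """GAS spring-tendon's contribution to knee joint power, in W."""
    m = morphology
    a_A, a_K = _relative_angles(state, m)
    f_gas = m.k_GAS * ((np.asarray(a_A, dtype=float) - a_K) * m.r_GAS - m.l_GAS_slack)
    if clamp_slack:
        f_gas = np.maximum(f_gas, 0.0)
    return np.asarray(state.omega_K, dtype=float) * m.r_GAS * f_gas


def motor_power(current, U_supply: float = 24.0):
    """Electrical joint power P = I_cal * U_supply per motor channel (W)."""
    return np.asarray(current, dtype=float) * U_supply


def net_positive_energy(powers, idle_power_per_driver: float = 0.0):
    """Mean net positive electrical power E_en in W.

    ``powers`` is a sequence of per-channel power series sharing one grid.
    Per sample: sum the channels, subtract the total idle power of the motor
    drivers, clip negative values to zero; then average.  The clip is applied
    to the summed series, not per channel.
    """
    if idle_power_per_driver < 0:
        raise ConfigurationError("idle power must be non-negative")
    powers = [np.asarray(p, dtype=float) for p in powers]
    total = np.sum(powers, axis=0) - idle_power_per_driver * len(powers)
    return float(np.mean(np.clip(total, 0.0, None)))


def cost_of_transport(E_en: float, m: float, v: float, g: float = 9.81) -> float:
    """Dimensionless COT = E_en / (m g v)."""
    if m <= 0 or g <= 0:
        raise ConfigurationError("mass and g must be positive")
    if v <= 0:
        raise ValueError("mean forward speed must be positive")
    return E_en / (m * g * v)


def relative_cot(cot: float, cot_nr: float = COT_NATURAL_RUNNER):
    """Relative COT in percent of a same-mass natural runner, raw and
    integer-rounded.  Returns ``(raw_percent, rounded_percent)``."""
    if cot_nr <= 0:
        raise ConfigurationError("reference COT must be positive")
    raw = cot / cot_nr * 100.0
    return raw, int(round(raw))


@dataclass
class EnergySummary:
    """Per-condition energetics: mean net positive power, speed, COT."""

    E_en: float
    m: float
    v: float
    g: float = 9.81
    cot_nr: float = COT_NATURAL_RUNNER
    idle_power_per_driver: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def cot(self) -> float:
        return cost_of_transport(self.E_en, self.m, self.v, self.g)

    @property
    def cot_re(self) -> float:
        return relative_cot(self.cot, self.cot_nr)[0]

    @property
    def cot_re_rounded(self) -> int:
        return relative_cot(self.cot, self.cot_nr)[1]

    def as_dict(self) -> dict:
        return {
            "E_en_W": self.E_en, "mass_kg": self.m, "speed_m_s": self.v,
            "COT": self.cot, "COT_nr": self.cot_nr,
            "COT_re_percent": self.cot_re,
            "COT_re_percent_rounded": self.cot_re_rounded,
            "idle_power_per_driver_W": self.idle_power_per_driver,
            **self.provenance,
        }
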