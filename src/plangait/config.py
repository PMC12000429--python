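"""Shared domain types, unit/phase conventions, and configuration validation.

All internal quantities are SI (rad, m, kg, s, A, V, W); degrees appear only
at I/O boundaries.  Angle conventions: ankle dorsiflexion positive with the
swing plateau near -22 deg, knee flexion positive with full extension at 0,
hip flexion positive.  Gait-cycle phase is expressed as percent of the cycle
(%GC) on the half-open interval [0, 100), 0 %GC at touch-down of the
reference (trailing) foot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import yaml

__all__ = [
    "ConfigurationError",
    "RobotMorphology",
    "ControlMode",
    "ControlParams",
    "AngleConvention",
    "FilterSettings",
    "validate_morphology",
    "to_percent_gc",
    "deg_to_rad",
    "rad_to_deg",
    "convert_angle",
    "load_config",
]

DEG = math.pi / 180.0


class ConfigurationError(ValueError):
    """Raised when a configuration value is missing, malformed, or invalid."""


class ControlMode(str, Enum):
    """Knee-flexion initiation mode of the experiment.

    AKFI: active knee flexion initiation (the knee motor commands flexion
    onset).  PKFI: passive initiation (knee motor torque is zeroed from
    mid-stance so flexion emerges from spring-tendon and reaction moments).
    PKFI40 shifts the zero-torque onset from 35 %GC to 40 %GC.
    """

    AKFI = "AKFI"
    PKFI = "PKFI"
    PKFI40 = "PKFI40"


# Default segment mass partition (fractions of total mass).  The per-segment
# masses are not published for this platform; a distal-light distribution is
# used and fully configurable.  Keys are segment names.
DEFAULT_MASS_FRACTIONS: dict[str, float] = {
    "trunk": 0.58,
    "thigh_L": 0.10,
    "thigh_R": 0.10,
    "shank_L": 0.07,
    "shank_R": 0.07,
    "foot_L": 0.04,
    "foot_R": 0.04,
}

DEFAULT_COM_FRACTIONS: dict[str, float] = {
    "trunk": 0.0,
    "thigh": 0.5,
    "shank": 0.5,
    "foot": 0.5,
}


@dataclass(frozen=True)
class RobotMorphology:
    """Geometric, elastic, mass, and electrical constants of the biped.

    Lengths in m, stiffnesses in N/m (linear) or N*m/rad (rotational),
    angles in rad, mass in kg.  ``k_toe`` is stored for completeness but the
    momentum analysis treats each foot as a single rigid segment, so it never
    enters an equation here.
    """

    l_thigh: float = 0.160
    l_shank: float = 0.160
    l_heel: float = 0.032
    l_toe: float = 0.017
    r_SOL: float = 0.013
    r_GAS: float = 0.013
    k_SOL: float = 4500.0          # 4.5 N/mm
    k_GAS: float = 1400.0          # 1.4 N/mm
    k_toe: float = 8.04e-3 * (180.0 / math.pi)  # 8.04 N*mm/deg -> N*m/rad
    l_SOL_slack: float = 0.0
    l_GAS_slack: float = 0.0
    alpha_A_slack: float = -22.0 * DEG
    alpha_K_slack: float = 0.0
    total_mass: float = 2.1
    segment_mass_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MASS_FRACTIONS)
    )
    segment_com_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COM_FRACTIONS)
    )
    U_supply: float = 24.0
    g: float = 9.81
    r_fourbar: float = 0.2         # lower-rod length mapping four-bar angle to trunk height

    @property
    def l_foot(self) -> float:
        return self.l_heel + self.l_toe

    def segment_mass(self, name: str) -> float:
        return self.total_mass * self.segment_mass_fractions[name]


@dataclass(frozen=True)
class ControlParams:
    """Central-pattern-generator control parameters (phase-oscillator CPG).

    ``f`` gait frequency in Hz; flexion factors and phases are fractions of
    the gait cycle; amplitudes/offsets in degrees as commanded.
    ``zero_torque_start`` applies only in the passive modes.  ``pd_gains`` is
    recorded metadata only and never used in any computation.
    """

    f: float = 1.0
    F_hip: float = 0.6
    F_knee: float = 0.6
    theta_kneeAmplitude: float = 55.0
    theta_kneeOffset: float = 8.0
    theta_hipAmplitude: float = 26.0
    theta_hipOffset: float = 12.0
    phi_hip: float = 0.05
    mode: ControlMode = ControlMode.AKFI
    zero_torque_start: float = 0.35
    phase_shift_lr: float = 0.5
    pd_gains: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ConfigurationError("gait frequency f must be > 0")
        for name in ("F_hip", "F_knee", "phi_hip", "zero_torque_start"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        for name in ("theta_kneeAmplitude", "theta_hipAmplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def period(self) -> float:
        return 1.0 / self.f


def params_for_mode(mode: ControlMode | str, **overrides) -> ControlParams:
    """Standard control parameters for a named experiment mode."""
    mode = ControlMode(mode)
    zts = {ControlMode.AKFI: 0.35, ControlMode.PKFI: 0.35, ControlMode.PKFI40: 0.40}
    kw = dict(mode=mode, zero_torque_start=zts[mode])
    kw.update(overrides)
    return ControlParams(**kw)


@dataclass(frozen=True)
class AngleConvention:
    """Documented sign convention; shipped in every output file's provenance."""

    ankle: str = "dorsiflexion positive; swing plateau ~ -22 deg"
    knee: str = "flexion positive; full extension 0"
    hip: str = "flexion positive"

    def as_dict(self) -> dict[str, str]:
        return {"ankle": self.ankle, "knee": self.knee, "hip": self.hip}


@dataclass(frozen=True)
class FilterSettings:
    """Zero-phase Butterworth low-pass settings per channel group.

    The published text fixes only the filter family (Butterworth, zero phase,
    second-order-sections realization); per-sensor orders and cutoffs live in
    an unavailable supplementary table, so these defaults are configurable and
    always echoed into output provenance.
    """

    order: int = 2
    cutoff_angles: float = 20.0    # Hz: joint angles, slider, four-bar
    cutoff_currents: float = 10.0  # Hz

    def cutoff_for(self, channel: str) -> float:
        return self.cutoff_currents if channel.startswith("I_") else self.cutoff_angles


def deg_to_rad(value):
    return value * DEG


def rad_to_deg(value):
    return value / DEG


def convert_angle(value, direction: str):
    """Exact linear deg<->rad conversion; ``direction`` in {deg2rad, rad2deg}."""
    if direction == "deg2rad":
        return deg_to_rad(value)
    if direction == "rad2deg":
        return rad_to_deg(value)
    raise ConfigurationError(f"unknown conversion direction {direction!r}")


def to_percent_gc(t: float, cycle_start: float, cycle_end: float) -> float:
    """Map an absolute time to percent of gait cycle in [0, 100).

    The interval is half-open: an event exactly at the next touch-down
    belongs to the next cycle.  Wrap-around is disallowed.
    """
    if not cycle_start < cycle_end:
        raise ValueError("cycle_start must precede cycle_end")
    if not (cycle_start <= t < cycle_end):
        raise ValueError(
            f"t={t} outside cycle [{cycle_start}, {cycle_end})"
        )
    return 100.0 * (t - cycle_start) / (cycle_end - cycle_start)


_UNIT_SCALES = {
    # raw-config unit -> SI multiplier, applied exactly once at validation
    "mm": 1e-3,
    "N/mm": 1e3,
    "Nmm/deg": 1e-3 * (180.0 / math.pi),
}

_POSITIVE_FIELDS = (
    "l_thigh", "l_shank", "l_heel", "l_toe", "r_SOL", "r_GAS",
    "k_SOL", "k_GAS", "k_toe", "total_mass", "U_supply", "g", "r_fourbar",
)


def validate_morphology(raw_config: Mapping | RobotMorphology | None = None) -> RobotMorphology:
    """Validate a morphology mapping (or an existing morphology) into a
    :class:`RobotMorphology`.

    Raw mappings may express lengths in mm, linear stiffness in N/mm, and
    rotational stiffness in N*mm/deg by suffixing the key with the unit,
    e.g. ``l_thigh_mm: 160`` or ``k_SOL_N/mm: 4.5``; conversion to SI is
    applied exactly once.  Validation is idempotent: re-validating a valid
    morphology returns an equal object.
    """
    if raw_config is None:
        raw_config = {}
    if isinstance(raw_config, RobotMorphology):
        kwargs = {}
    else:
        kwargs = {}
        for key, value in dict(raw_config).items():
            base = key
            for unit, scale in _UNIT_SCALES.items():
                suffix = "_" + unit
                if key.endswith(suffix):
                    base = key[: -len(suffix)]
                    value = float(value) * scale
                    break
            if base in ("alpha_A_slack_deg", "alpha_K_slack_deg"):
                base = base[:-4]
                value = deg_to_rad(float(value))
            kwargs[base] = value
        unknown = set(kwargs) - set(RobotMorphology.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown morphology fields: {sorted(unknown)}")
    morpho = (
        raw_config if isinstance(raw_config, RobotMorphology) else RobotMorphology(**kwargs)
    )

    for name in _POSITIVE_FIELDS:
        v = getattr(morpho, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ConfigurationError(f"morphology field {name} must be strictly positive, got {v}")
    fractions = dict(morpho.segment_mass_fractions)
    expected = set(DEFAULT_MASS_FRACTIONS)
    if set(fractions) != expected:
        raise ConfigurationError(
            f"segment_mass_fractions must have keys {sorted(expected)}, got {sorted(fractions)}"
        )
    if any(f < 0 for f in fractions.values()) or abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ConfigurationError(
            "segment_mass_fractions must be non-negative and sum to 1 within 1e-9 "
            f"(sum={sum(fractions.values())!r})"
        )
    for seg, frac in morpho.segment_com_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"segment_com_fraction[{seg}] must lie in [0, 1]")
    # normalize mapping containers so equality/idempotence is well defined
    return replace(
        morpho,
        segment_mass_fractions=dict(fractions),
        segment_com_fractions=dict(morpho.segment_com_fractions),
    )


def load_config(path) -> dict:
    """Load a YAML configuration with optional sections
    ``morphology``, ``control``, ``filtering``, ``synthesis``, ``analysis``.

    Returns a dict with validated ``morphology`` (RobotMorphology),
    ``control`` (ControlParams), ``filtering`` (FilterSettings) and the raw
    remaining sections.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    out["morphology"] = validate_morphology(raw.get("morphology", {}))
    ctrl = dict(raw.get("control", {}))
    mode = ctrl.pop("mode", "AKFI")
    out["control"] = params_for_mode(mode, **ctrl)
    out["filtering"] = FilterSettings(**raw.get("filtering", {}))
    out["synthesis"] = dict(raw.get("synthesis", {}))
    out["analysis"] = dict(raw.get("analysis", {}))
    return out
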