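"""End-to-end analysis: raw log -> events, impulses, energetics, report.

The stages mirror the measurement chain: linear interpolation to a uniform
1000 Hz grid, zero-phase Butterworth filtering, touch-down segmentation into
gait cycles (first 120 kept by default), per-cycle event detection, planar
forward kinematics and segmental momentum partition, transition-window
impulses, and electrical energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energetics as en
from . import events as ev
from . import kinetics as kin
from . import prep
from .config import AngleConvention, FilterSettings, RobotMorphology, validate_morphology
from .log import CURRENT_CHANNELS, TimeSeriesLog, UniformLog
from .synth import SyntheticScenario, simulate

__all__ = ["ConditionResult", "analyze_log", "run_experiment"]


@dataclass
class ConditionResult:
    """All per-condition outputs of the analysis pipeline."""

    condition: str
    events: ev.GaitEvents
    impulses: pd.DataFrame          # per-cycle transition impulses
    ensemble: prep.CycleEnsemble
    energy: en.EnergySummary
    mean_speed: float
    momentum_example: kin.MomentumSeries | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def events_table(self) -> pd.DataFrame:
        return self.events.per_cycle

    def impulse_summary(self) -> pd.DataFrame:
        cols = [c for c in self.impulses.columns if c != "cycle"]
        return pd.DataFrame({
            "mean": self.impulses[cols].mean(),
            "sd": self.impulses[cols].std(ddof=0),
        })


def _momentum_series_for_cycle(
    ensemble: prep.CycleEnsemble,
    cycle: int,
    morphology: RobotMorphology,
    trailing_side: str,
) -> kin.MomentumSeries:
    """Per-cycle segmental momenta from the cycle's resampled traces."""
    n_points = len(ensemble.gc_grid)
    period = float(ensemble.periods()[cycle])
    rate = n_points / period
    channels = {name: ensemble.cycles[name][cycle] for name in ensemble.cycles}
    positions = kin.forward_kinematics(channels, morphology)
    momenta = {
        name: kin.segment_momentum(
            morphology.segment_mass(name), np.gradient(pos, axis=0) * rate
        )
        for name, pos in positions.items()
    }
    p_TL, p_RB, p_CoM = kin.partition_momentum(momenta, morphology, trailing_side)
    leading = "R" if trailing_side == "L" else "L"
    m_TL = sum(morphology.segment_mass(f"{s}_{trailing_side}")
               for s in ("foot", "shank", "thigh"))
    masses = {"TL": m_TL,
              "RB": morphology.total_mass - m_TL,
              "CoM": morphology.total_mass}
    return kin.MomentumSeries(gc=ensemble.gc_grid, p_TL=p_TL, p_RB=p_RB,
                              p_CoM=p_CoM, masses=masses)


def analyze_log(
    log: TimeSeriesLog | UniformLog,
    morphology: RobotMorphology | None = None,
    filtering: FilterSettings | None = None,
    n_cycles: int = 120,
    trailing_side: str = "L",
    rate: float = 1000.0,
    idle_power_per_driver: float = 0.0,
    condition: str | None = None,
) -> ConditionResult:
    """Run the full analysis chain on one condition's sensor log."""
    morphology = morphology or validate_morphology()
    filtering = filtering or FilterSettings()
    if isinstance(log, TimeSeriesLog):
        uniform = prep.resample_uniform(log, rate)
    else:
        uniform = log
    filtered = prep.filter_log(uniform, filtering)

    td = prep.detect_touchdowns(filtered.channels[f"ankle_{trailing_side}"],
                                filtered.rate)
    boundaries = filtered.t0 + td
    ensemble = prep.segment_cycles(filtered, boundaries, n_keep=n_cycles)

    gait_events = ev.extract_events(ensemble, AngleConvention(),
                                    trailing_side=trailing_side)

    # per-cycle transition impulses
    rows = []
    example = None
    ev_by_cycle = gait_events.per_cycle.set_index("cycle")
    for c in range(ensemble.n_cycles):
        series = _momentum_series_for_cycle(ensemble, c, morphology, trailing_side)
        try:
            window = kin.find_transition_window(series.v_CoM[:, 1], series.gc)
            t_lltd = (float(ev_by_cycle.loc[c, "t_LLTD"])
                      if c in ev_by_cycle.index else None)
            imp = kin.impulse_over_window(series, window, t_lltd)
        except (prep.DetectionError, ValueError):
            continue
        if example is None:
            example = series
        row = {"cycle": c, "t_vmin": imp.t_vmin, "t_vmax": imp.t_vmax,
               "dv_angle_deg": imp.velocity_angle_change_deg}
        for part in ("TL", "RB", "CoM"):
            row[f"dp_{part}_x"] = imp.delta[part][0]
            row[f"dp_{part}_y"] = imp.delta[part][1]
            row[f"dp_{part}_mag"] = imp.delta_mag[part]
        rows.append(row)
    impulses = pd.DataFrame(rows)

    # energetics: mean speed from the slider over the kept cycles
    t0, t1 = ensemble.boundaries[0], ensemble.boundaries[-1]
    i0, i1 = filtered.time_to_index(t0), filtered.time_to_index(t1)
    sx = filtered.channels["slider_x"]
    mean_speed = float((sx[i1] - sx[i0]) / (t1 - t0))
    powers = [en.motor_power(filtered.channels[ch][i0:i1], morphology.U_supply)
              for ch in CURRENT_CHANNELS]
    E_en = en.net_positive_energy(powers, idle_power_per_driver)
    energy = en.EnergySummary(
        E_en=E_en, m=morphology.total_mass, v=mean_speed,
        g=morphology.g, idle_power_per_driver=idle_power_per_driver,
        provenance={"n_cycles": ensemble.n_cycles},
    )

    provenance = {
        "condition": condition or uniform.metadata.get("condition", "unknown"),
        "filtering": {"order": filtering.order,
                      "cutoff_angles_hz": filtering.cutoff_angles,
                      "cutoff_currents_hz": filtering.cutoff_currents},
        "angle_convention": AngleConvention().as_dict(),
        "n_cycles": ensemble.n_cycles,
        "trailing_side": trailing_side,
    }
    truth_meta = uniform.metadata.get("truth", {})
    for key in ("schedule_seed", "noise_seed", "scenario_seed"):
        if key in uniform.metadata:
            provenance[key] = uniform.metadata[key]
        elif key in truth_meta:
            provenance[key] = truth_meta[key]
    return ConditionResult(
        condition=provenance["condition"], events=gait_events,
        impulses=impulses, ensemble=ensemble, energy=energy,
        mean_speed=mean_speed, momentum_example=example, provenance=provenance,
    )


def run_experiment(
    scenario: SyntheticScenario,
    noiseless: bool = False,
    **analyze_kwargs,
):
    """Simulate a scenario and analyze it; returns (result, truth)."""
    log, truth = simulate(scenario, noiseless=noiseless)
    result = analyze_log(log, morphology=scenario.morphology,
                         n_cycles=scenario.n_cycles,
                         condition=scenario.control.mode.value,
                         **analyze_kwargs)
    return result, truth
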