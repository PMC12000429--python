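"""Detect the five gait events and check them against the generator schedule.

The detectors work purely from joint kinematics: ankle-reversal extrema for
plantarflexion onset (SAPF) and toe-off (TO), and 1 rad/s gradient
thresholds for leading-leg touch-down (LLTD) and hip/knee flexion onsets
(SHF, SKF).  On synthetic logs the scheduled times are known, so the
detector loop can be closed: mean absolute recovery error should stay well
below 0.5 %GC.
"""

import numpy as np

from plangait import SyntheticScenario, params_for_mode
from plangait.pipeline import run_experiment

scenario = SyntheticScenario(control=params_for_mode("PKFI"), n_cycles=30, seed=7)
result, truth = run_experiment(scenario)

table = result.events.per_cycle
print(result.events.summary().round(2))
print(f"\ncycles analyzed: {len(table)}, excluded: {len(result.events.excluded)}")

print("\nrecovery error vs scheduled ground truth (%GC):")
idx = table["cycle"].to_numpy()
for name in ("t_SKF", "t_SHF", "t_SAPF", "t_LLTD", "t_TO"):
    err = table[name].to_numpy() - np.asarray(truth["events_gc"][name])[idx]
    print(f"  {name:7s} mean|err| = {np.mean(np.abs(err)):.3f}")

delta = table["delta_SAPF_LLTD"].mean()
print(f"\nSAPF - LLTD = {delta:+.2f} %GC: with passive initiation the ankle "
      "reversal follows the leading-leg touch-down")
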