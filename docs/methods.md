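# Methods

This note documents the models, conventions, numerical choices, and the
synthetic-data generator behind `plangait`, and what the passing test suite
does and does not establish about real robot data.

## Conventions and units

All internal quantities are SI; degrees appear only at I/O boundaries.
Angles: ankle dorsiflexion-positive with the swing plateau near −22°
(the spring-tendon slack calibration pose), knee flexion-positive with full
extension at 0, hip flexion-positive. Gait-cycle phase is percent of the
cycle on the half-open interval [0, 100), 0 %GC at the trailing foot's
touch-down; an event exactly at the next touch-down belongs to the next
cycle. The platform's drawings do not fix printed sign conventions, so this
choice is internally consistent rather than hardware-verified; it is
recorded in every output file's provenance.

Morphology defaults (validated, unit-converted exactly once):
thigh = shank = 160 mm, heel 32 mm, toe 17 mm, pulley radii 13 mm,
k_SOL = 4.5 N/mm, k_GAS = 1.4 N/mm, toe spring 8.04 N·mm/°
(stored but unused — each foot is one rigid segment in the momentum
analysis), total mass 2.1 kg, supply 24 V. Segment mass fractions are not
published; the default distal-light partition {trunk 0.58, thigh 0.10 ×2,
shank 0.07 ×2, foot 0.04 ×2} is configurable, and every cross-condition
result is either mass-free or compares the two conditions under the same
partition.

## Signal preparation

Raw logs are sampled when each control loop completes (~600 Hz with ~±20 %
spacing jitter). Analysis interpolates linearly to 1000 Hz and applies
zero-phase (forward–backward) Butterworth low-pass filters realized in
second-order sections — effective attenuation is the squared single-pass
magnitude. The per-sensor orders/cutoffs are not published; defaults are
order 2 with 20 Hz (angles, slider, four-bar) and 10 Hz (currents), fully
configurable and echoed into provenance. Edge handling uses scipy's
even-reflection padding (3× the section length); tests that assert
zero-phase symmetry exclude the padded edges.

Touch-down detection arms on a swing plateau (|dθ/dt| < 0.2 rad/s for
≥ 100 ms) and fires at the first sample with |dθ/dt| > 1 rad/s — the same
gradient threshold the event detectors use. The first 120 complete cycles
are kept; each is resampled to a common 1000-point %GC grid for ensemble
statistics, while event detection runs on the per-cycle traces with the
cycle's true duration setting the rad/s scale.

## Event detectors

All detectors operate on filtered signals; gradients are central differences
(one-sided at edges); a threshold crossing is the first strict inequality;
ties break to the earliest sample.

* **SAPF** — argmax of the trailing ankle angle within a stance search
  window (default [10, 90] %GC, configurable; whether the original analysis
  windowed this search is unknown). The window avoids the touch-down
  transient claiming the maximum.
* **TO** — most negative ankle gradient after SAPF, then the angle minimum
  within the following 40 ms (truncated at the cycle end).
* **LLTD** — last instant before TO at which the *leading* (contralateral)
  ankle's |gradient| exceeds 1 rad/s. The leading leg's trace is read on the
  trailing leg's cycle clock, with no re-segmentation.
* **SHF** — first hip gradient > 1 rad/s after peak hip extension (the hip
  minimum in the flexion-positive convention).
* **SKF** — first knee gradient > 1 rad/s within [SHF − 0.2 s, SHF + 0.1 s],
  clamped to the cycle.

Cycles on which any detector fails are excluded and listed, never silently
dropped; more than 10 % failures aborts aggregation.

## Kinetics

Forward kinematics of the 7-segment planar body: the hip point sits at
(slider_x, r_fourbar·sin(four-bar angle)) — the four-bar rod length is not
published, so the vertical mapping uses a configurable r_fourbar
(default 0.2 m); trunk rotations are locked. Thigh hangs at the hip angle
from vertical, shank at (hip − knee), and the foot points forward at
(hip − knee + ankle) from horizontal; each CoM sits at its configured
fraction along its segment. CoM velocities are central-difference gradients
of the filtered positions — the same numeric convention as the event
detectors.

Momenta p_i = m_i·v_i are summed into the trailing leg (foot + shank +
thigh of the push-off side), the remaining body (leading leg + trunk), and
the CoM; additivity p_CoM = p_TL + p_RB holds exactly by construction and
propagates to all impulses. The transition window is the global minimum of
vertical CoM velocity within the push-off half of the cycle (default
[25, 75] %GC) to the *second* local maximum after it; peaks qualify with a
relative prominence of 10 % of the post-minimum range, which keeps noise
wiggles from claiming second place. If only one peak exists the detector
raises unless a single-peak fallback is explicitly enabled. Impulses are
endpoint differences of the momentum series; the momentum values at LLTD
are reported as the intermediate timepoint. "Kinetic energy" of a
multi-segment part defaults to the aggregate form |p|²/(2m) — which tracks
the part's velocity vector — with the per-segment Σ½mv² available
separately.

## Energetics

Tendon extensions are measured relative to the slack calibration pose
(ankle −22°, knee 0°, slack lengths 0 mm): α in the power equations means
(angle − calibration angle), otherwise the printed slack setting would
imply nonzero force at the calibration pose. The literal piecewise ankle
power (GAS engaged when α_A ≥ α_K) is the default; an optional clamp floors
each tendon force at zero because a physical tendon cannot push — the
printed equations have no clamp, so both paths exist and are tested. On the
engaged branch, P_A − P_K,GAS is the exact time derivative of the stored
elastic energy, and the SOL-only loop integral vanishes on closed ankle
trajectories — both verified numerically to 1e−6.

Electrical power is I·24 V per motor channel. Net positive power E_en:
sum the four channels, subtract the drivers' idle power (default 0 W — the
hardware value is not published and must be supplied to reproduce
hardware-like energetics), clip negatives to zero *after* summation, then
average. E_en is read as mean power (W), the only dimensionally consistent
reading of COT = E_en/(m g v). The natural-runner reference COT is an input
constant (1.36 at 2.1 kg); the allometric formula behind it is not
implemented.

## Statistics

Twelve measures (t_SKF, t_SAPF, Δt_SAPF−LLTD; Δ|p|, Δp_x, Δp_y for TL, RB,
CoM) are compared with a paired two-sided Wilcoxon signed-rank test, cycles
paired by index. Zero differences are discarded by default (classic
Wilcoxon; a rank-splitting variant is available — continuity of the robot
signals makes zeros rare, so determinism mattered more than the variant
choice). For n ≤ 12 the p-value is exact, enumerating all 2ⁿ sign
assignments of the observed ranks (ties included); above that, a normal
approximation with tie and continuity corrections. No multiple-testing
correction is applied, matching per-measure reporting at α = 0.001; the
report footer states this. Δt_SAPF−LLTD is reported as t_SAPF − t_LLTD,
negative when the ankle reversal precedes the leading-leg touch-down.

## The synthetic generator

The generator emulates the statistical structure of the robot's logs, not
its dynamics: piecewise-smooth (cosine/Hermite) joint-angle segments
parameterized only by the CPG table quantities (1 Hz, knee 55° over an 8°
offset, hip 26° over 12°, 5 % hip hold, half-cycle left–right shift) and a
per-cycle event schedule. Schedules draw per-event Gaussian jitter
(SD 0.3 %GC, emulating sub-0.4 %GC robot repeatability) around
condition means: AKFI {SKF 39.00, SHF 40.50, SAPF 46.25, LLTD 47.87,
TO 62.0} and PKFI {SKF 43.67, SHF 44.50, SAPF 48.77, LLTD 46.89, TO 64.0}
%GC. SHF and TO means are not published numerically and were fixed once
from the published event ordering (hip flexion 4 %GC later with PKFI; TO
between SAPF and vmax); the LLTD means place the SAPF−LLTD interval at
−1.62/+1.88 %GC, matching the published ±2 %GC sign change.

Ground-truth semantics follow the detectors: scheduled SHF/SKF are the
instants the noiseless gradient crosses +1 rad/s (reversals accelerate at
50 rad/s², putting the crossing 20 ms after motion onset); scheduled LLTD
is the end of the leading ankle's touch-down transient (2 rad/s for 10 ms,
linear decay to 0.5 rad/s, last 1 rad/s crossing exactly at LLTD); SAPF and
TO are parabolic-cap extrema with equal edge slopes, so the zero-phase
filter does not displace them. Peak knee flexion sits at a fixed 71 % of
the cycle in both conditions — a later (passive) onset therefore flexes
faster, which is the kinematic signature of the catapult release. The hip
swing likewise ends at the 95 % hold in both conditions.

The trunk channels are *solved*, not drawn: given the leg kinematics, the
slider and four-bar series are integrated so the whole-body CoM velocity
follows a per-condition hodograph profile (period 50 %GC, piecewise-cosine
with extrema exactly at its knots) anchored to the published transition
values — horizontal 0.41 m/s at the second peak in both conditions,
vertical 0.14/0.13 m/s, and endpoint differences matching the published CoM
impulses (0.12/0.79 vs 0.16/0.66 kg·m/s horizontally/vertically). vmin sits
just before LLTD and vmax ~4 %GC after TO in both conditions. Motor-current
bumps during hip swing and knee flexion are scaled so the net positive
power matches the published condition energetics (COT 0.56/0.52 at
0.44 m/s); the passive condition's knee channel carries a reduced bump.
The sensor model redraws timestamps with ±20 % spacing jitter around
600 Hz, quantizes angle channels to their encoder resolutions (5000 CPR
hip/knee, 4096 CPR ankle/four-bar), and adds small Gaussian noise; all
randomness is seeded and reproducible.

**What the generator does not emulate:** contact dynamics and ground
reaction forces, torque-level PD control, impact transients beyond the
stylized touch-down ramp, treadmill-speed feedback, soft-tissue damping,
sensor dropouts, and drift. Passing tests therefore show that the analysis
chain is *correct and self-consistent* (it recovers known schedules to
≤ 0.5 %GC, preserves additivity, reproduces the published ordinal condition
contrasts and arithmetic identities) — not that the detectors are robust to
every artifact of physical data. Absolute impulse magnitudes of the
surrogate are smaller than the hardware's (the kinematic legs lack true
push-off loading); cross-condition *orderings*, timing statistics, and
energetics are the meaningful surfaces.

## Problem sizes

Tests and the acceptance script use the standard study size — 120 cycles
per condition at 1000 Hz analysis rate — which runs in seconds; smaller
runs (6–30 cycles) are used where a property does not depend on the
ensemble size.

## Known limitations

* The event-timing means for SHF/TO, the four-bar rod length, the segment
  mass partition, and the drivers' idle power are unpublished; all are
  configurable inputs with documented defaults.
* The CPG reference trajectories are published only through their table
  parameters; `cpg_reference_trajectory` reconstructs commanded curves that
  honor those constraints but is not the original oscillator integrator.
* The ~20 %GC shift between CPG phase and observed touch-down is modeled as
  a single configurable offset and does not enter the analysis chain.
* Wilcoxon p-values below ~1e−15 are reported as 0 by the normal
  approximation; significance calls at α = 0.001 are unaffected.
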