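import numpy as np
import pytest

from plangait.config import ConfigurationError, params_for_mode
from plangait.log import ANGLE_CHANNELS
from plangait.synth import (
    CONTACT_TO_LLTD,
    NoiseModel,
    SyntheticScenario,
    apply_sensor_model,
    cpg_reference_trajectory,
    schedule_ground_truth,
    simulate,
    synthesize_joint_angles,
)

PHASE = np.linspace(0.0, 1.0, 2000, endpoint=False)


@pytest.fixture(scope="module")
def noiseless_akfi():
    from plangait import validate_morphology
    sched = schedule_ground_truth(params_for_mode("AKFI"), 6, seed=3,
                                  jitter_sd=0.0)
    log = synthesize_joint_angles(sched, params_for_mode("AKFI"),
                                  validate_morphology())
    return sched, log


class TestCpgReference:
    def test_zero_knee_amplitude_gives_constant_offset(self):
        params = params_for_mode("AKFI", theta_kneeAmplitude=0.0)
        _, knee = cpg_reference_trajectory(params, PHASE)
        assert np.allclose(knee, np.radians(8.0))

    def test_knee_excursion_equals_commanded_amplitude(self):
        _, knee = cpg_reference_trajectory(params_for_mode("AKFI"), PHASE)
        assert np.degrees(knee.max() - knee.min()) == pytest.approx(55.0, abs=1e-9)

    def test_hip_stays_within_offset_plus_minus_amplitude(self):
        hip, _ = cpg_reference_trajectory(params_for_mode("AKFI"), PHASE)
        lo, hi = np.radians(12.0 - 26.0), np.radians(12.0 + 26.0)
        assert hip.min() >= lo - 1e-12 and hip.max() <= hi + 1e-12

    def test_left_right_are_half_cycle_shifted(self):
        params = params_for_mode("AKFI")
        hip_l, knee_l = cpg_reference_trajectory(params, PHASE, side="L")
        hip_r, knee_r = cpg_reference_trajectory(params, PHASE, side="R")
        half = len(PHASE) // 2
        assert np.allclose(np.roll(hip_l, -half), hip_r, atol=1e-12)
        assert np.allclose(np.roll(knee_l, -half), knee_r, atol=1e-12)


class TestSchedule:
    def test_zero_jitter_reproduces_condition_means(self):
        sched = schedule_ground_truth(params_for_mode("AKFI"), 10, seed=0,
                                      jitter_sd=0.0)
        assert np.allclose(sched.events["t_SAPF"], 46.25)
        assert np.allclose(sched.events["t_SKF"], 39.00)

    def test_passive_condition_reversal_follows_touchdown(self):
        sched = schedule_ground_truth(params_for_mode("PKFI"), 10, seed=0,
                                      jitter_sd=0.0)
        delta = sched.events["t_SAPF"] - sched.events["t_LLTD"]
        assert np.all(delta > 0)

    def test_active_condition_reversal_precedes_touchdown(self):
        sched = schedule_ground_truth(params_for_mode("AKFI"), 10, seed=0,
                                      jitter_sd=0.0)
        assert np.all(sched.events["t_SAPF"] - sched.events["t_LLTD"] < 0)

    def test_seeded_schedule_is_bit_identical(self):
        a = schedule_ground_truth(params_for_mode("PKFI"), 50, seed=42)
        b = schedule_ground_truth(params_for_mode("PKFI"), 50, seed=42)
        for name in a.events:
            assert np.array_equal(a.events[name], b.events[name])
        assert np.array_equal(a.periods, b.periods)

    def test_condition_contrast_of_knee_flexion_onset(self):
        a = schedule_ground_truth(params_for_mode("AKFI"), 120, seed=1)
        p = schedule_ground_truth(params_for_mode("PKFI"), 120, seed=2)
        diff = p.events["t_SKF"].mean() - a.events["t_SKF"].mean()
        assert diff == pytest.approx(4.67, abs=0.15)

    def test_bad_means_rejected(self):
        with pytest.raises(ConfigurationError):
            schedule_ground_truth(
                params_for_mode("AKFI"), 10, seed=0,
                means={"t_SKF": 50.0, "t_SHF": 40.0, "t_SAPF": 46.0,
                       "t_LLTD": 47.0, "t_TO": 62.0},
            )


class TestSynthesizedCurves:
    def test_stance_ankle_maximum_at_scheduled_reversal(self, noiseless_akfi):
        sched, log = noiseless_akfi
        truth = log.metadata["truth"]
        t = log.times
        for c in range(3):
            t0 = truth["boundaries_s"][c]
            T = truth["periods_s"][c]
            m = (t >= t0) & (t < t0 + T)
            seg = log.channels["ankle_L"][m]
            gc = 100.0 * (t[m] - t0) / T
            assert gc[np.argmax(seg)] == pytest.approx(46.25, abs=0.1)

    def test_swing_plateau_is_exactly_constant(self, noiseless_akfi):
        sched, log = noiseless_akfi
        truth = log.metadata["truth"]
        t = log.times
        t0, T = truth["boundaries_s"][1], truth["periods_s"][1]
        m = (t >= t0 + 0.75 * T) & (t < t0 + 0.98 * T)
        assert np.std(log.channels["ankle_L"][m]) < 1e-9

    def test_denser_sampling_refines_the_same_curves(self):
        sched = schedule_ground_truth(params_for_mode("AKFI"), 3, seed=4,
                                      jitter_sd=0.0)
        morpho = __import__("plangait").validate_morphology()
        lo = synthesize_joint_angles(sched, params_for_mode("AKFI"), morpho,
                                     rate=1000.0)
        hi = synthesize_joint_angles(sched, params_for_mode("AKFI"), morpho,
                                     rate=2000.0)
        interp = np.interp(hi.times, lo.times, lo.channels["knee_L"])
        quantum = 2 * np.pi / 5000
        assert np.max(np.abs(interp - hi.channels["knee_L"])) < quantum

    def test_leading_leg_contact_offset_matches_lltd(self, noiseless_akfi):
        # the leading ankle leaves its plateau CONTACT_TO_LLTD before the
        # scheduled LLTD instant
        assert CONTACT_TO_LLTD == pytest.approx(0.020)

    def test_invalid_rate_rejected(self, noiseless_akfi):
        sched, _ = noiseless_akfi
        with pytest.raises(ConfigurationError):
            synthesize_joint_angles(sched, params_for_mode("AKFI"),
                                    __import__("plangait").validate_morphology(),
                                    rate=0.0)


class TestSensorModel:
    def _noiseless_log(self, n_cycles=3, rate=600.0):
        sched = schedule_ground_truth(params_for_mode("AKFI"), n_cycles,
                                      seed=5, jitter_sd=0.0)
        return synthesize_joint_angles(sched, params_for_mode("AKFI"),
                                       __import__("plangait").validate_morphology(),
                                       rate=rate)

    def test_identity_when_noise_free_on_same_grid(self):
        log = self._noiseless_log(rate=600.0)
        noise = NoiseModel(sampling_rate_nominal=600.0, sampling_jitter=0.0,
                           encoder_counts={}, angle_noise_sd=0.0,
                           slider_noise_sd=0.0, current_noise_sd=0.0, seed=0)
        out = apply_sensor_model(log, noise)
        n = len(out.timestamps)
        assert np.allclose(out.timestamps, log.times[:n], atol=1e-12)
        for name in ANGLE_CHANNELS:
            assert np.allclose(out.channels[name], log.channels[name][:n],
                               atol=1e-12)

    def test_hip_channel_quantized_to_encoder_steps(self):
        log = self._noiseless_log()
        out = apply_sensor_model(log, NoiseModel(angle_noise_sd=0.0, seed=1))
        q = 2 * np.pi / 5000
        vals = out.channels["hip_L"]
        assert np.allclose(vals, np.round(vals / q) * q, atol=1e-12)
        q_ankle = 2 * np.pi / 4096
        vals = out.channels["ankle_R"]
        assert np.allclose(vals, np.round(vals / q_ankle) * q_ankle, atol=1e-12)

    def test_same_seed_reproduces_log(self):
        log = self._noiseless_log()
        a = apply_sensor_model(log, NoiseModel(seed=11))
        b = apply_sensor_model(log, NoiseModel(seed=11))
        assert np.array_equal(a.timestamps, b.timestamps)
        assert all(np.array_equal(a.channels[k], b.channels[k]) for k in a.channels)

    def test_median_spacing_is_robot_like(self):
        log, _ = simulate(SyntheticScenario(n_cycles=3, seed=9))
        assert 1 / 1200 <= log.median_spacing() <= 1 / 300
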