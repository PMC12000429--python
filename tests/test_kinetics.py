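import numpy as np
import pytest

from plangait.kinetics import (
    SEGMENT_NAMES,
    MomentumSeries,
    aggregate_kinetic_energy,
    find_transition_window,
    forward_kinematics,
    impulse_over_window,
    partition_momentum,
    segment_momentum,
    velocity_angle_change,
)
from plangait.prep import DetectionError, InputError


def _pose(morphology, **overrides):
    base = {name: 0.0 for name in
            ("hip_L", "hip_R", "knee_L", "knee_R", "ankle_L", "ankle_R",
             "slider_x", "fourbar")}
    base.update(overrides)
    return forward_kinematics(base, morphology)


class TestForwardKinematics:
    def test_straight_leg_spans_thigh_plus_shank(self, morphology):
        pos = _pose(morphology)
        hip_y = pos["trunk"][1]
        # ankle sits one full foot CoM fraction into the foot; reconstruct
        # the ankle joint from the shank CoM instead
        shank = pos["shank_L"]
        ankle_y = hip_y - morphology.l_thigh - morphology.l_shank
        assert shank[1] == pytest.approx(hip_y - morphology.l_thigh
                                         - 0.5 * morphology.l_shank)
        assert (hip_y - ankle_y) == pytest.approx(0.320)

    def test_pure_slider_translation_moves_every_com(self, morphology):
        a = _pose(morphology)
        b = _pose(morphology, slider_x=0.25)
        for name in SEGMENT_NAMES:
            assert np.allclose(b[name] - a[name], [0.25, 0.0], atol=1e-12)

    def test_right_angle_knee_offsets_ankle_by_shank_length(self, morphology):
        a = _pose(morphology)
        b = _pose(morphology, knee_L=np.pi / 2)
        # shank CoM moves by l_shank/2 horizontally and l_shank/2 vertically
        dx = b["shank_L"][0] - a["shank_L"][0]
        assert abs(dx) == pytest.approx(0.5 * morphology.l_shank, abs=1e-12)

    def test_missing_channel_raises(self, morphology):
        with pytest.raises(InputError, match="fourbar"):
            forward_kinematics({"hip_L": 0.0}, morphology)


class TestMomentum:
    def test_componentwise_product(self):
        assert np.allclose(segment_momentum(0.3, (1.0, 0.0)), [0.3, 0.0])
        assert np.allclose(segment_momentum(0.3, (0.0, 0.0)), [0.0, 0.0])

    def test_rigid_motion_sums_to_total_mass_times_velocity(self, morphology):
        v = np.array([0.44, -0.05])
        momenta = {name: segment_momentum(morphology.segment_mass(name), v)
                   for name in SEGMENT_NAMES}
        total = sum(momenta.values())
        assert np.allclose(total, morphology.total_mass * v, atol=1e-12)

    def test_partition_additivity_is_exact(self, morphology):
        rng = np.random.default_rng(0)
        momenta = {name: rng.standard_normal((500, 2)) for name in SEGMENT_NAMES}
        p_tl, p_rb, p_com = partition_momentum(momenta, morphology, "L")
        assert np.array_equal(p_com, p_tl + p_rb)

    def test_relabeling_trailing_side_swaps_parts(self, morphology):
        rng = np.random.default_rng(1)
        momenta = {name: rng.standard_normal(2) for name in SEGMENT_NAMES}
        tl_l, rb_l, com_l = partition_momentum(momenta, morphology, "L")
        tl_r, rb_r, com_r = partition_momentum(momenta, morphology, "R")
        assert np.allclose(com_l, com_r, atol=1e-15)
        assert np.allclose(tl_l + tl_r + momenta["trunk"], com_l, atol=1e-14)

    def test_resting_trailing_leg_gives_com_equal_rb(self, morphology):
        momenta = {name: np.array([0.1, 0.2]) for name in SEGMENT_NAMES}
        for seg in ("foot_L", "shank_L", "thigh_L"):
            momenta[seg] = np.zeros(2)
        p_tl, p_rb, p_com = partition_momentum(momenta, morphology, "L")
        assert np.allclose(p_tl, 0.0)
        assert np.array_equal(p_com, p_rb)


class TestTransitionWindow:
    def _series(self, vmin_gc=45.0, peaks=(55.0, 65.0), depth=-0.2, heights=(0.13, 0.13)):
        gc = np.linspace(0, 100, 1000, endpoint=False)
        v = np.zeros_like(gc)
        v += depth * np.exp(-((gc - vmin_gc) / 2.5) ** 2)
        for p, h in zip(peaks, heights):
            v += h * np.exp(-((gc - p) / 2.5) ** 2)
        return gc, v

    def test_second_of_two_similar_peaks_selected(self):
        gc, v = self._series()
        t_vmin, t_vmax = find_transition_window(v, gc)
        assert t_vmin == pytest.approx(45.0, abs=0.2)
        assert t_vmax == pytest.approx(65.0, abs=0.2)

    def test_monotone_series_raises(self):
        gc = np.linspace(0, 100, 1000, endpoint=False)
        with pytest.raises((DetectionError, ValueError)):
            find_transition_window(gc / 100.0, gc)

    def test_single_peak_needs_explicit_fallback(self):
        gc, v = self._series(peaks=(55.0,), heights=(0.13,))
        with pytest.raises(DetectionError):
            find_transition_window(v, gc)
        t_vmin, t_vmax = find_transition_window(v, gc, allow_single_peak=True)
        assert t_vmax == pytest.approx(55.0, abs=0.3)


def _const_series(gc, p_tl, p_rb, masses):
    n = len(gc)
    return MomentumSeries(
        gc=gc,
        p_TL=np.tile(p_tl, (n, 1)).astype(float),
        p_RB=np.tile(p_rb, (n, 1)).astype(float),
        p_CoM=np.tile(np.add(p_tl, p_rb), (n, 1)).astype(float),
        masses=masses,
    )


class TestImpulses:
    GC = np.linspace(0, 100, 1000, endpoint=False)
    MASSES = {"TL": 0.441, "RB": 1.659, "CoM": 2.1}

    def test_constant_momentum_gives_zero_impulse(self):
        s = _const_series(self.GC, [0.1, 0.0], [0.5, 0.1], self.MASSES)
        imp = impulse_over_window(s, (45.0, 65.0))
        for part in ("TL", "RB", "CoM"):
            assert np.allclose(imp.delta[part], 0.0, atol=1e-12)
            assert imp.delta_mag[part] == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_trailing_leg_impulse_by_subtraction(self):
        s = _const_series(self.GC, [0.1, 0.0], [0.5, 0.1], self.MASSES)
        ramp = np.interp(self.GC, [0, 45, 65, 100], [0.0, 0.0, 0.17, 0.17])
        s.p_TL[:, 0] += ramp
        s.p_CoM[:, 0] += ramp
        imp = impulse_over_window(s, (45.0, 65.0))
        assert imp.delta["TL"][0] == pytest.approx(0.17, abs=1e-9)

    def test_com_impulse_is_sum_of_parts(self):
        rng = np.random.default_rng(2)
        n = len(self.GC)
        p_tl = np.cumsum(rng.standard_normal((n, 2)), axis=0) * 1e-3
        p_rb = np.cumsum(rng.standard_normal((n, 2)), axis=0) * 1e-3
        s = MomentumSeries(gc=self.GC, p_TL=p_tl, p_RB=p_rb, p_CoM=p_tl + p_rb,
                           masses=self.MASSES)
        imp = impulse_over_window(s, (30.0, 70.0))
        assert np.allclose(imp.delta["CoM"],
                           imp.delta["TL"] + imp.delta["RB"], atol=1e-9)

    def test_window_outside_grid_rejected(self):
        s = _const_series(self.GC, [0.1, 0.0], [0.5, 0.1], self.MASSES)
        with pytest.raises(ValueError):
            impulse_over_window(s, (45.0, 120.0))

    def test_impulse_matches_integrated_momentum_gradient(self, akfi_noiseless):
        result, _ = akfi_noiseless
        series = result.momentum_example
        gc = series.gc
        window = (40.0, 70.0)
        i0, i1 = np.searchsorted(gc, window)
        grad = np.gradient(series.p_TL[:, 0], gc)
        integrated = np.trapezoid(grad[i0:i1 + 1], gc[i0:i1 + 1])
        imp = impulse_over_window(series, (gc[i0], gc[i1]))
        assert imp.delta["TL"][0] == pytest.approx(integrated, abs=1e-6)


class TestVelocityAngleAndEnergy:
    def test_identical_vectors_have_zero_angle(self):
        assert velocity_angle_change([0.4, 0.1], [0.4, 0.1]) == 0.0

    def test_upward_redirection_angle(self):
        angle = velocity_angle_change([1.0, -0.1], [1.0, 0.1])
        assert angle == pytest.approx(np.degrees(2 * np.arctan(0.1)), abs=1e-9)
        assert angle > 0

    def test_scale_invariance(self):
        a = velocity_angle_change([0.3, -0.05], [0.35, 0.08])
        b = velocity_angle_change([0.6, -0.10], [0.70, 0.16])
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            velocity_angle_change([0.0, 0.0], [1.0, 0.0])

    def test_whole_body_energy_at_transition_end(self):
        # |p| = 0.9387 kg m/s over 2.1 kg -> ~0.21 J
        e = aggregate_kinetic_energy(np.array([0.9387, 0.0]), 2.1)
        assert e == pytest.approx(0.21, abs=0.005)

    def test_rigid_body_energy(self):
        v = np.array([0.44, 0.0])
        e = aggregate_kinetic_energy(2.1 * v, 2.1)
        assert e == pytest.approx(0.5 * 2.1 * 0.44**2)

    def test_rest_is_zero(self):
        assert aggregate_kinetic_energy(np.zeros(2), 2.1) == 0.0
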