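import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plangait.events import (
    detect_lltd,
    detect_sapf,
    detect_shf,
    detect_skf,
    detect_to,
    extract_events,
    time_gradient,
)
from plangait.prep import DetectionError

RATE = 1000.0
N = 1000  # one 1 s cycle at 1000 Hz -> 0.1 %GC per sample


class TestTimeGradient:
    def test_affine_series_gives_constant_slope(self):
        t = np.arange(100) / RATE
        g = time_gradient(2.0 + 3.0 * t, RATE)
        assert np.allclose(g, 3.0, atol=1e-9)

    def test_constant_gives_zero(self):
        assert np.allclose(time_gradient(np.full(50, 1.0), RATE), 0.0)

    def test_sinusoid_against_analytic_derivative(self):
        t = np.arange(2000) / RATE
        g = time_gradient(np.sin(2 * np.pi * t), RATE)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(g[1:-1] - expected[1:-1])) < 1e-3


def _stance_reversal_trace(peak_gc=46.25):
    """Rise to a maximum at peak_gc then fall (dorsiflexion-positive)."""
    gc = np.linspace(0, 100, N, endpoint=False)
    return -0.38 + 0.28 * np.exp(-((gc - peak_gc) / 18.0) ** 2)


class TestSapf:
    def test_reversal_located_at_maximum(self):
        assert detect_sapf(_stance_reversal_trace()) == pytest.approx(46.25, abs=0.1)

    def test_plateau_maximum_resolves_to_earliest_sample(self):
        trace = _stance_reversal_trace()
        k = int(np.argmax(trace))
        trace[k: k + 3] = trace[k]
        assert detect_sapf(trace) == pytest.approx(100.0 * k / N)

    def test_monotone_trace_has_no_reversal(self):
        with pytest.raises(DetectionError):
            detect_sapf(np.linspace(-0.4, 0.1, N))


class TestToeOff:
    def _push_off_trace(self, to_gc=62.0):
        # dorsiflexion ramp to 46 %GC, then plantarflexion whose steepest
        # descent sits just before the plateau arrival at to_gc
        gc = np.linspace(0, 100, N, endpoint=False)
        trace = np.full(N, -0.384)
        stance = gc < 46.0
        trace[stance] = -0.384 + 0.28 * np.sin(np.pi * gc[stance] / 92.0)
        drop = (gc >= 46.0) & (gc < to_gc)
        s = (gc[drop] - 46.0) / (to_gc - 46.0)
        top = trace[gc < 46.0][-1]
        trace[drop] = -0.384 + (top + 0.384) * np.cos(np.pi * s / 2)
        return trace

    def test_toe_off_at_plateau_arrival(self):
        assert detect_to(self._push_off_trace(), RATE, t_sapf=46.0) == pytest.approx(
            62.0, abs=1.0)

    def test_window_truncated_at_cycle_end(self):
        trace = self._push_off_trace(to_gc=99.5)
        t = detect_to(trace, RATE, t_sapf=46.0)
        assert t < 100.0

    def test_two_equal_minima_resolve_to_earliest(self):
        trace = self._push_off_trace()
        t1 = detect_to(trace, RATE, t_sapf=46.0)
        k = int(round(t1 / 100 * N))
        trace[k + 5] = trace[k]  # duplicate the minimum later in the window
        assert detect_to(trace, RATE, t_sapf=46.0) == t1

    def test_no_negative_gradient_raises(self):
        with pytest.raises(DetectionError):
            detect_to(np.linspace(-0.4, 0.0, N), RATE, t_sapf=10.0)


class TestLltd:
    def test_last_crossing_before_toe_off(self):
        gc = np.linspace(0, 100, N, endpoint=False)
        trace = np.full(N, -0.384)
        burst = (gc >= 47.0) & (gc < 49.0)
        trace[burst] = -0.384 + 2.0 * (gc[burst] - 47.0) / 100.0  # 2 rad/s
        trace[gc >= 49.0] = trace[burst][-1]
        t = detect_lltd(trace, RATE, t_to=62.0, threshold=1.0)
        assert t == pytest.approx(49.0, abs=0.2)

    def test_subthreshold_gradient_raises(self):
        gc = np.linspace(0, 100, N, endpoint=False)
        trace = 0.5 * gc / 100.0  # 0.5 rad/s everywhere
        with pytest.raises(DetectionError):
            detect_lltd(trace, RATE, t_to=62.0, threshold=1.0)

    @given(st.floats(0.5, 3.0), st.floats(0.0, 1.0))
    def test_raising_threshold_never_moves_lltd_later(self, thr, dthr):
        gc = np.linspace(0, 100, N, endpoint=False)
        trace = np.full(N, -0.384)
        burst = (gc >= 40.0) & (gc < 50.0)
        # gradient decays linearly from 4 rad/s to 0 across the burst
        g = 4.0 * (1 - (gc[burst] - 40.0) / 10.0)
        trace[burst] = -0.384 + np.cumsum(g) / RATE
        trace[gc >= 50.0] = trace[burst][-1]
        try:
            t_low = detect_lltd(trace, RATE, 62.0, thr)
        except DetectionError:
            return
        try:
            t_high = detect_lltd(trace, RATE, 62.0, thr + dthr)
        except DetectionError:
            return
        assert t_high <= t_low


class TestShfSkf:
    def _hip_trace(self, shf_gc=40.5):
        gc = np.linspace(0, 100, N, endpoint=False)
        trace = np.where(gc < shf_gc, -0.24 + 0.0 * gc, 0.0)
        rise = gc >= shf_gc
        trace[rise] = -0.24 + 2.0 * (gc[rise] - shf_gc) / 100.0  # 2 rad/s
        return trace

    def test_first_crossing_after_peak_extension(self):
        t = detect_shf(self._hip_trace(), RATE, threshold=1.0)
        assert t == pytest.approx(40.5, abs=0.2)

    def test_flat_hip_trace_raises(self):
        with pytest.raises(DetectionError):
            detect_shf(np.zeros(N), RATE)

    def test_knee_crossing_inside_window(self):
        gc = np.linspace(0, 100, N, endpoint=False)
        knee = np.where(gc < 39.0, 0.14, 0.14)
        rise = gc >= 39.0
        knee = knee.astype(float)
        knee[rise] = 0.14 + 3.0 * (gc[rise] - 39.0) / 100.0
        t = detect_skf(knee, RATE, t_shf=40.5, threshold=1.0)
        assert t == pytest.approx(39.0, abs=0.2)

    def test_quiet_knee_raises(self):
        with pytest.raises(DetectionError):
            detect_skf(np.full(N, 0.14), RATE, t_shf=40.5)


class TestExtractEvents:
    def test_event_ordering_on_synthetic_defaults(self, akfi_noiseless):
        result, _ = akfi_noiseless
        t = result.events.per_cycle
        assert (t["t_SKF"] <= t["t_SHF"]).all()
        assert (t["t_SHF"] <= t["t_SAPF"]).all()
        assert (t["t_SAPF"] < t["t_TO"]).all()

    def test_corrupted_cycle_is_reported_not_dropped_silently(self, akfi_noiseless):
        result, _ = akfi_noiseless
        ens = result.ensemble
        ens_bad = type(ens)(
            gc_grid=ens.gc_grid, boundaries=ens.boundaries,
            cycles={k: v.copy() for k, v in ens.cycles.items()},
        )
        ens_bad.cycles["hip_L"][3] = 0.0  # flat hip -> SHF failure
        events = extract_events(ens_bad)
        assert len(events.excluded) == 1
        assert events.excluded[0][0] == 3
        assert 3 not in events.per_cycle["cycle"].to_numpy()

    def test_recovered_event_spread_matches_injected_jitter(self, akfi_noisy):
        result, _ = akfi_noisy
        sds = result.events.per_cycle[
            ["t_SKF", "t_SHF", "t_SAPF", "t_LLTD", "t_TO"]].std(ddof=0)
        # 0.3 %GC injected; detection adds little variance
        assert ((sds >= 0.2) & (sds <= 0.45)).all()
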