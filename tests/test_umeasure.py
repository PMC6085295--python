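import numpy as np
import pytest

from uwave.averaging import AverageBeat
from uwave.io_ecg import ConfigurationError
from uwave.umeasure import estimate_baseline, measure_u_amplitude, measure_u_wave


FS = 500.0


def beat_with(amp_fn, pre_ms=250.0, post_ms=650.0, fs=FS):
    pre = int(round(pre_ms / 1000 * fs))
    post = int(round(post_ms / 1000 * fs))
    t = (np.arange(-pre, post + 1)) / fs * 1000.0
    return AverageBeat(t, amp_fn(t), fs, 10)


def gaussian_bump(apex_uv=40.0, center=520.0, width=40.0):
    return lambda t: apex_uv * np.exp(-0.5 * ((t - center) / width) ** 2)


class TestBaseline:
    def test_zero_signal_gives_zero(self):
        avg = beat_with(lambda t: np.zeros_like(t))
        assert estimate_baseline(avg, "AF") == 0.0

    def test_constant_offset_moves_baseline_not_u_amp(self):
        avg0 = beat_with(gaussian_bump())
        avg1 = beat_with(lambda t: gaussian_bump()(t) + 25.0)
        b0, b1 = estimate_baseline(avg0, "AF"), estimate_baseline(avg1, "AF")
        assert b1 - b0 == pytest.approx(25.0)
        m0 = measure_u_amplitude(avg0, b0)
        m1 = measure_u_amplitude(avg1, b1)
        assert m1.u_amp_uV == pytest.approx(m0.u_amp_uV, abs=1e-6)

    def test_linear_drift_baseline_is_midwindow_value(self):
        # drift 1 uV per 10 ms; 10-sample window ending at R-60ms covers
        # t = -80..-62 ms -> mean is the drift value at the window midpoint
        slope = 0.1  # uV/ms
        avg = beat_with(lambda t: slope * t)
        base = estimate_baseline(avg, "AF", qrs_onset_offset_ms=60.0)
        mid_t = np.mean(np.arange(-80, -60, 2.0))  # sample times in window
        assert base == pytest.approx(slope * mid_t, abs=slope * 2.0)

    def test_sr_mode_uses_p_onset_offset(self):
        # a step 30 uV that starts at -100 ms: the SR window (ending at
        # R-220 ms) sits before it, the AF window (ending at R-60) inside it
        avg = beat_with(lambda t: np.where(t >= -100.0, 30.0, 0.0))
        assert estimate_baseline(avg, "SR") == pytest.approx(0.0)
        assert estimate_baseline(avg, "AF") == pytest.approx(30.0)

    def test_window_outside_beat_is_configuration_error(self):
        avg = beat_with(lambda t: np.zeros_like(t), pre_ms=50.0)
        with pytest.raises(ConfigurationError, match="window_pre_ms"):
            estimate_baseline(avg, "AF")


class TestUMeasurement:
    def test_flat_beat_has_no_u_wave(self):
        avg = beat_with(lambda t: np.zeros_like(t))
        m = measure_u_amplitude(avg, 0.0)
        assert m.u_amp_uV == 0.0 and not m.u_present

    @pytest.mark.parametrize("apex", [40.0, -40.0])
    def test_planted_bump_recovered(self, apex):
        avg = beat_with(gaussian_bump(apex))
        m = measure_u_amplitude(avg, 0.0)
        assert m.u_amp_uV == pytest.approx(apex, abs=2.0)
        assert m.u_peak_time_ms == pytest.approx(520.0, abs=10.0)
        assert m.u_present

    def test_point_method_matches_fit_on_clean_bump(self):
        avg = beat_with(gaussian_bump())
        f = measure_u_amplitude(avg, 0.0, apex_method="fit")
        p = measure_u_amplitude(avg, 0.0, apex_method="point")
        assert f.u_amp_uV == pytest.approx(p.u_amp_uV, abs=0.5)

    def test_scaling_beat_scales_u_amp(self):
        avg = beat_with(gaussian_bump())
        scaled = beat_with(lambda t: 2.5 * gaussian_bump()(t))
        m1 = measure_u_amplitude(avg, 0.0)
        m2 = measure_u_amplitude(scaled, 0.0)
        assert m2.u_amp_uV == pytest.approx(2.5 * m1.u_amp_uV, rel=1e-3)

    def test_apex_on_window_edge_not_called_present(self):
        # monotone ramp: extremum sits on the search-window edge
        avg = beat_with(lambda t: 0.1 * t)
        m = measure_u_amplitude(avg, 0.0)
        assert not m.u_present

    def test_below_noise_floor_not_present(self):
        avg = beat_with(gaussian_bump(6.0))
        m = measure_u_amplitude(avg, 0.0, noise_floor_uV=10.0)
        assert abs(m.u_amp_uV) < 10.0 and not m.u_present

    def test_search_window_clipped_to_beat_extent(self):
        avg = beat_with(gaussian_bump())
        m = measure_u_amplitude(avg, 0.0, search_window_ms=(450.0, 900.0))
        assert m.search_window_ms[1] == pytest.approx(650.0)

    def test_search_window_beyond_beat_is_error(self):
        avg = beat_with(gaussian_bump())
        with pytest.raises(ConfigurationError):
            measure_u_amplitude(avg, 0.0, search_window_ms=(700.0, 800.0))


def test_measure_u_wave_convenience_runs_both_stages():
    avg = beat_with(lambda t: gaussian_bump()(t) + 5.0)
    m = measure_u_wave(avg, mode="AF")
    assert m.baseline_uV == pytest.approx(5.0, abs=0.1)
    assert m.u_amp_uV == pytest.approx(40.0, abs=2.0)
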