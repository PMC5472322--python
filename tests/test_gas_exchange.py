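import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anacap import (
    BreathSeries,
    accumulated_vo2,
    isotime,
    mean_last_window,
    read_breaths,
    resample_uniform,
    truncate,
    write_breaths,
)


def exp_series(amp=2.0, tau=30.0, duration=300.0, dt=2.0):
    t = np.arange(dt, duration + dt / 2, dt)
    v = amp * (1.0 - np.exp(-t / tau))
    return BreathSeries(t=t, vo2=v, vco2=0.85 * v)


class TestBreathSeriesValidation:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BreathSeries(t=[0, 2, 1], vo2=[1, 1, 1], vco2=[1, 1, 1])

    def test_negative_gas_rates_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            BreathSeries(t=[0, 1], vo2=[1, -0.1], vco2=[1, 1])

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            BreathSeries(t=[0, 1], vo2=[1, 1, 1], vco2=[1, 1])


class TestCsvRoundTrip:
    def test_write_then_read_preserves_values(self, tmp_path):
        s = exp_series()
        path = tmp_path / "bout.csv"
        write_breaths(s, path)
        back = read_breaths(path)
        np.testing.assert_allclose(back.t, s.t, atol=1e-6)
        np.testing.assert_allclose(back.vo2, s.vo2, atol=1e-6)
        np.testing.assert_allclose(back.vco2, s.vco2, atol=1e-6)

    def test_reversed_time_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_s,vo2_l_min,vco2_l_min\n2,1.0,0.9\n1,1.0,0.9\n")
        with pytest.raises(ValueError, match="strictly increasing"):
            read_breaths(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("t_s,vo2_l_min,vco2_l_min\n")
        with pytest.raises(ValueError, match="no breaths"):
            read_breaths(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("t_s,vo2_l_min\n1,1.0\n")
        with pytest.raises(ValueError, match="vco2_l_min"):
            read_breaths(path)

    def test_comment_lines_and_extra_columns_tolerated(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "# analyzer export\nt_s,vo2_l_min,vco2_l_min,hr_bpm\n1,1.0,0.9,120\n2,1.1,0.95,125\n"
        )
        s = read_breaths(path)
        assert len(s) == 2


class TestResample:
    def test_constant_stays_constant(self, make_constant_series):
        rs = resample_uniform(make_constant_series(2.0), 1.0)
        np.testing.assert_allclose(rs.vo2, 2.0)

    def test_linear_midpoint(self):
        s = BreathSeries(t=[0.0, 10.0], vo2=[1.0, 2.0], vco2=[1.0, 2.0])
        rs = resample_uniform(s, 5.0)
        np.testing.assert_allclose(rs.t, [0.0, 5.0, 10.0])
        assert rs.vo2[1] == pytest.approx(1.5)

    def test_endpoints_preserved(self):
        s = exp_series(duration=301.3)
        rs = resample_uniform(s, 1.0)
        assert rs.t[0] == s.t[0]
        assert rs.t[-1] == s.t[-1]

    def test_single_breath_rejected(self):
        s = BreathSeries(t=[1.0], vo2=[2.0], vco2=[1.7])
        with pytest.raises(ValueError, match="at least 2"):
            resample_uniform(s)

    def test_resampled_exponential_integral_matches_closed_form(self):
        # ∫ A(1−e^{−t/τ}) dt over [t0, T] has a closed form; the 1-Hz
        # trapezoid on 2-s breaths must agree within 0.5%.
        amp, tau = 2.0, 30.0
        s = exp_series(amp, tau, 300.0)
        t0, T = s.t[0], s.t[-1]
        exact = amp * ((T - t0) + tau * (np.exp(-T / tau) - np.exp(-t0 / tau)))
        got = accumulated_vo2(s, t0, T) * 60.0
        assert got == pytest.approx(exact, rel=5e-3)


class TestMeanLastWindow:
    def test_constant(self, make_constant_series):
        s = make_constant_series(2.99, duration=60.0)
        assert mean_last_window(s, 30.0) == pytest.approx(2.99)

    def test_linear_ramp_analytic(self):
        # ramp of slope k ending at v: window mean is v − k·window/2
        k, window = 0.01, 30.0
        t = np.arange(0.0, 120.5, 0.5)
        v = 0.5 + k * t
        s = BreathSeries(t=t, vo2=v, vco2=v)
        assert mean_last_window(s, window) == pytest.approx(v[-1] - k * window / 2, rel=1e-6)

    def test_short_series_rejected(self, make_constant_series):
        s = make_constant_series(duration=20.0)
        with pytest.raises(ValueError, match="shorter than window"):
            mean_last_window(s, 30.0)

    def test_invariant_to_breaths_before_window(self):
        t = np.arange(1.0, 201.0)
        v = 2.0 + 0.3 * np.sin(t / 11.0)
        full = BreathSeries(t=t, vo2=v, vco2=v)
        late = BreathSeries(t=t[100:], vo2=v[100:], vco2=v[100:])
        assert mean_last_window(full, 30.0) == pytest.approx(mean_last_window(late, 30.0))


class TestAccumulatedVO2:
    def test_constant_rate(self, make_constant_series):
        s = make_constant_series(3.0, duration=120.0)
        got = accumulated_vo2(s, s.t[0], s.t[-1])
        # 3 L·min⁻¹ sustained for the sampled span
        assert got == pytest.approx(3.0 * (s.t[-1] - s.t[0]) / 60.0, rel=1e-9)

    def test_exponential_closed_form(self):
        # vo2(t) = 2(1−e^{−t/30}): ∫ over [1, 300] s has a closed form just
        # above 9 L; the trapezoid on the sampled series must match to 0.2%.
        s = exp_series(2.0, 30.0, 300.0, dt=1.0)
        t0, T = 1.0, 300.0
        exact = 2.0 * ((T - t0) + 30.0 * (np.exp(-T / 30) - np.exp(-t0 / 30))) / 60.0
        got = accumulated_vo2(s, t0, T)
        assert got == pytest.approx(exact, rel=2e-3)

    def test_degenerate_window_rejected(self, make_constant_series):
        s = make_constant_series()
        with pytest.raises(ValueError, match="strictly before"):
            accumulated_vo2(s, 10.0, 10.0)

    def test_window_outside_series_rejected(self, make_constant_series):
        s = make_constant_series(duration=120.0)
        with pytest.raises(ValueError, match="outside"):
            accumulated_vo2(s, 0.0, 500.0)

    @settings(derandomize=True, max_examples=25)
    @given(split=st.floats(min_value=3.0, max_value=295.0))
    def test_additive_over_adjacent_windows(self, split):
        s = exp_series(2.0, 30.0, 300.0)
        t0, T = s.t[0], s.t[-1]
        whole = accumulated_vo2(s, t0, T)
        parts = accumulated_vo2(s, t0, split) + accumulated_vo2(s, split, T)
        assert parts == pytest.approx(whole, rel=1e-6)
        assert whole >= 0


class TestTruncate:
    def test_truncation_interpolates_endpoint(self):
        s = BreathSeries(t=[0.0, 10.0], vo2=[1.0, 2.0], vco2=[1.0, 2.0])
        cut = truncate(s, 5.0)
        assert cut.t[-1] == 5.0
        assert cut.vo2[-1] == pytest.approx(1.5)

    def test_truncation_beyond_end_is_noop(self, make_constant_series):
        s = make_constant_series()
        assert truncate(s, 1e9) is s


class TestIsotime:
    def test_takes_shorter_time(self):
        assert isotime(298.3, 400.0) == pytest.approx(298.3)

    def test_equal_times(self):
        assert isotime(100.0, 100.0) == 100.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            isotime(-1.0, 50.0)
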