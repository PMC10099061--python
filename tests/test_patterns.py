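import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fescycling import (
    CircularInterval,
    DelayModel,
    MuscleForceProfile,
    StimulationPattern,
    compensate,
    delay_to_shift,
    full_range_pattern,
    measure_shift,
    mfp_pattern,
    threshold_pattern,
)
from conftest import profile_from_function


def make_mfp(fn, bin_width=1.0):
    return MuscleForceProfile(
        muscle="right_quadriceps",
        side="right",
        profile=profile_from_function(fn, bin_width=bin_width),
        cadence=50.0,
    )


def raised_cosine(arc_start, arc_len, peak=50.0):
    def fn(th):
        u = ((th - arc_start) % 360.0) / arc_len
        return peak * 0.5 * (1 - np.cos(2 * np.pi * u)) if u <= 1 else 0.0

    return fn


def brute_force_best_window(values, bin_width, length_deg):
    """Independent oracle: naive scan of every window placement."""
    n = len(values)
    win = max(1, min(int(round(length_deg / bin_width)), n))
    best_start, best_sum = None, -np.inf
    for k in range(n):
        s = 0.0
        for j in range(win):
            s += values[(k + j) % n]
        if s > best_sum + 1e-12:
            best_sum = s
            best_start = k
    return best_start * bin_width  # window covers bins k .. k+win-1


class TestMfpPattern:
    def test_window_equal_to_support_recovers_it(self):
        m = make_mfp(raised_cosine(330, 120))
        iv = mfp_pattern(m, 120)
        assert iv.start == pytest.approx(330, abs=0.51)
        assert iv.length == pytest.approx(120)

    def test_shorter_window_centers_on_peak(self):
        """A 60-degree window over a bump on [330, 90] (peak at 30) is
        placed at [0, 60] (verified by exhaustive placement)."""
        m = make_mfp(raised_cosine(330, 120))
        iv = mfp_pattern(m, 60)
        assert iv.start == pytest.approx(0, abs=0.51)
        assert iv.stop == pytest.approx(60, abs=0.51)

    def test_constant_profile_tie_breaks_to_smallest_start(self):
        m = make_mfp(lambda th: 1.0)
        iv = mfp_pattern(m, 90)
        assert iv.start == pytest.approx(0, abs=0.51)

    def test_nowhere_positive_rejected(self):
        m = make_mfp(lambda th: -1.0)
        with pytest.raises(ValueError, match="contributing"):
            mfp_pattern(m, 90)

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            values = rng.standard_normal(360)
            m = make_mfp(lambda th: 0.0)
            m.profile.values[:] = values
            length = float(rng.integers(10, 200))
            iv = mfp_pattern(m, length)
            expected_start = brute_force_best_window(values, 1.0, length)
            assert iv.start == pytest.approx(expected_start, abs=1e-9)


class TestFullRangeAndThreshold:
    def test_full_range_matches_analytic_zeros(self):
        m = make_mfp(raised_cosine(330, 120))
        iv = full_range_pattern(m)
        assert iv.start == pytest.approx(330, abs=1.0)
        assert iv.stop == pytest.approx(90, abs=1.0)

    def test_full_range_of_sine(self):
        m = make_mfp(lambda th: np.sin(np.deg2rad(th)))
        iv = full_range_pattern(m)
        assert iv.start == pytest.approx(0, abs=1.0) or iv.start > 359.0
        assert iv.stop == pytest.approx(180, abs=1.0)

    def test_strictly_positive_profile_warns_full_circle(self):
        m = make_mfp(lambda th: 1.0 + 0.1 * np.cos(np.deg2rad(th)))
        with pytest.warns(UserWarning, match="full-circle"):
            iv = full_range_pattern(m)
        assert iv.length == pytest.approx(360)

    def test_threshold_zero_equals_full_range(self):
        m = make_mfp(raised_cosine(330, 120))
        a = full_range_pattern(m)
        b = threshold_pattern(m, 0.0)
        assert b.start == pytest.approx(a.start, abs=1.0)
        assert b.stop == pytest.approx(a.stop, abs=1.0)

    def test_half_max_width_of_raised_cosine(self):
        """A raised cosine spends exactly half its arc at or above half
        amplitude, centered on the peak."""
        m = make_mfp(raised_cosine(330, 120, peak=50.0))
        iv = threshold_pattern(m, 0.5)
        assert iv.length == pytest.approx(60, abs=1.5)
        center = (iv.start + iv.length / 2) % 360
        assert center == pytest.approx(30, abs=1.0)

    def test_high_fraction_shrinks_to_peak_neighborhood(self):
        m = make_mfp(raised_cosine(330, 120))
        iv = threshold_pattern(m, 0.999)
        assert iv.length < 10
        assert iv.contains(30.0)

    @settings(derandomize=True, max_examples=30)
    @given(f1=st.floats(0.05, 0.9), f2=st.floats(0.05, 0.9))
    def test_threshold_length_non_increasing(self, f1, f2):
        lo, hi = sorted((f1, f2))
        m = make_mfp(raised_cosine(200, 150))
        assert threshold_pattern(m, hi).length <= threshold_pattern(m, lo).length + 1e-9


class TestDelayToShift:
    def test_study_delays_give_sixteen_degrees(self):
        """D_S = 3.2 ms plus EMD = 50.1 ms at 50 rpm shifts the start by
        (53.3 ms) * 6 * 50 = 15.99 degrees, the printed 16-degree shift."""
        d_start, d_stop = delay_to_shift(DelayModel(d_s=0.0032, emd=0.0501), 50.0)
        assert d_start == pytest.approx(15.99)
        assert d_stop == pytest.approx(0.96)

    def test_zero_delays(self):
        assert delay_to_shift(DelayModel(0.0, 0.0), 50.0) == (0.0, 0.0)

    def test_eighty_ms_gives_twentyfour_degrees(self):
        d_start, _ = delay_to_shift(DelayModel(d_s=0.08, emd=0.0), 50.0)
        assert d_start == pytest.approx(24.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        d_s=st.floats(0, 0.05),
        emd=st.floats(0, 0.1),
        omega=st.floats(1, 100),
        scale=st.floats(0.1, 3.0),
    )
    def test_linearity_and_difference_identity(self, d_s, emd, omega, scale):
        d_start, d_stop = delay_to_shift(DelayModel(d_s, emd), omega)
        assert d_start - d_stop == pytest.approx(emd * 6.0 * omega, rel=1e-9, abs=1e-9)
        s_start, _ = delay_to_shift(DelayModel(d_s, emd), omega * scale)
        assert s_start == pytest.approx(d_start * scale, rel=1e-9, abs=1e-9)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            DelayModel(-0.01, 0.0)


class TestCompensate:
    def _pattern(self, start, stop):
        return StimulationPattern(channels={"left_quadriceps": CircularInterval(start, stop)})

    def test_start_only_shift(self):
        """A 16-degree start-only compensation of [200, 350] yields
        [184, 350] (the left-quadriceps row of a compensated pattern)."""
        out = compensate(self._pattern(200, 350), DelayModel(0.0032, 0.0501), 50.0)
        iv = out.channels["left_quadriceps"]
        assert iv.start == pytest.approx(200 - 15.99)
        assert iv.stop == pytest.approx(350)
        assert out.compensated and out.delays is not None

    def test_zero_shift_is_identity(self):
        out = compensate(self._pattern(100, 200), DelayModel(0.0, 0.0), 50.0)
        iv = out.channels["left_quadriceps"]
        assert (iv.start, iv.stop) == (pytest.approx(100), pytest.approx(200))

    def test_wraparound(self):
        out = compensate(self._pattern(5.0, 100.0), DelayModel(d_s=16.0 / 300.0, emd=0.0), 50.0)
        assert out.channels["left_quadriceps"].start == pytest.approx(349.0)

    def test_double_compensation_rejected(self):
        once = compensate(self._pattern(100, 200), DelayModel(0.0032, 0.0501), 50.0)
        with pytest.raises(ValueError, match="already"):
            compensate(once, DelayModel(0.0032, 0.0501), 50.0)

    def test_modular_round_trip(self):
        delays = DelayModel(0.0032, 0.0501)
        out = compensate(self._pattern(10, 120), delays, 50.0, mode="start_and_stop")
        d_start, d_stop = delay_to_shift(delays, 50.0)
        back = out.channels["left_quadriceps"].shifted(d_start, d_stop)
        assert back.start == pytest.approx(10)
        assert back.stop == pytest.approx(120)


class TestMeasureShift:
    def test_zero_delay_zero_shift(self):
        """Net-force rising exactly at the commanded start measures ~0 lag."""

        def net(th):
            return 30.0 if 40 <= th < 110 else 0.0

        m = make_mfp(net)
        assert measure_shift(m, 40.0) == pytest.approx(0.0, abs=1.0)

    def test_known_offset_recovered(self):
        def net(th):
            return 30.0 if 56 <= th < 110 else 0.0

        m = make_mfp(net)
        assert measure_shift(m, 40.0) == pytest.approx(16.0, abs=1.0)

    def test_no_response_raises(self):
        def net(th):
            return 30.0 if 250 <= th < 300 else 0.0

        m = make_mfp(net)
        with pytest.raises(ValueError, match="no measurable response"):
            measure_shift(m, 40.0)
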