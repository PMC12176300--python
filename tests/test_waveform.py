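"""Waveform reconstruction and phase mapping: the pi/2-peak convention,
amplitude/phase identities, day-angle round trips and cross-species window
alignment against closed-form answers."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclescope import (
    DayWindow,
    PeriodogramPeak,
    PhaseWindow,
    SinusoidFit,
    TimeSeries,
    align_species,
    assign_phase_labels,
    day_at_angle,
    day_window_to_phase,
    fit_waveform,
    phase_angle,
    phase_to_day_window,
)

TWO_PI = 2 * math.pi


def _peak(f):
    return PeriodogramPeak(frequency=f, period=1 / f, power=1.0, grid_index=0)


def _fit_with_peak_at(period, peak_day, amplitude=1.0, C=0.0):
    """Closed-form fit whose waveform peaks exactly at ``peak_day``."""
    phi = 0.5 * math.pi - TWO_PI * peak_day / period
    return SinusoidFit(
        frequency=1 / period,
        A=amplitude * math.cos(phi),
        B=amplitude * math.sin(phi),
        C=C,
    )


class TestFitWaveform:
    def test_pure_sine_recovers_quadrature_coefficients(self):
        t = np.linspace(0, 40, 400)
        ts = TimeSeries("a", t, np.sin(2 * np.pi * t / 10))
        fit = fit_waveform(ts, _peak(1 / 10))
        assert fit.A == pytest.approx(1.0, abs=1e-8)
        assert fit.B == pytest.approx(0.0, abs=1e-8)
        assert fit.C == pytest.approx(0.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-8)
        assert fit.phase_offset == pytest.approx(0.0, abs=1e-8)

    def test_pure_cosine_gives_phase_pi_over_two(self):
        t = np.linspace(0, 40, 400)
        ts = TimeSeries("a", t, np.cos(2 * np.pi * t / 10))
        fit = fit_waveform(ts, _peak(1 / 10))
        assert fit.A == pytest.approx(0.0, abs=1e-8)
        assert fit.B == pytest.approx(1.0, abs=1e-8)
        assert fit.phase_offset == pytest.approx(math.pi / 2, abs=1e-8)

    def test_six_point_series_coefficients_match_oracle(
        self, six_point_series, brute_fit
    ):
        f = 0.2
        fit = fit_waveform(six_point_series, _peak(f))
        beta, _ = brute_fit(six_point_series.times, six_point_series.values, f)
        assert (fit.A, fit.B, fit.C) == pytest.approx(tuple(beta), abs=1e-10)

    @given(
        A=st.floats(-5, 5), B=st.floats(-5, 5), C=st.floats(-3, 3),
        period=st.floats(2, 60),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_amplitude_phase_identity(self, A, B, C, period):
        # A sin(wt) + B cos(wt) + C == R sin(wt + phi) + C
        fit = SinusoidFit(frequency=1 / period, A=A, B=B, C=C)
        t = np.linspace(0, 2 * period, 101)
        w = TWO_PI * t / period
        lhs = fit.predict(t)
        rhs = fit.amplitude * np.sin(w + fit.phase_offset) + C
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestPhaseConvention:
    def test_peak_day_maps_to_pi_over_two(self):
        fit = SinusoidFit(frequency=0.1, A=1.0, B=0.0, C=0.0)
        assert phase_angle(fit, 2.5) == pytest.approx(math.pi / 2)

    def test_trough_day_maps_to_three_pi_over_two(self):
        fit = SinusoidFit(frequency=0.1, A=1.0, B=0.0, C=0.0)
        assert phase_angle(fit, 7.5) == pytest.approx(3 * math.pi / 2)

    def test_phase_is_periodic(self):
        fit = SinusoidFit(frequency=1 / 7.3, A=0.4, B=-1.1, C=2.0)
        for t in [0.0, 1.9, 5.5]:
            assert phase_angle(fit, t + 7.3) == pytest.approx(
                phase_angle(fit, t), abs=1e-9
            )

    def test_zero_amplitude_phase_undefined(self):
        fit = SinusoidFit(frequency=0.1, A=0.0, B=0.0, C=1.0)
        with pytest.raises(ValueError):
            phase_angle(fit, 1.0)

    @given(
        A=st.floats(-5, 5), B=st.floats(-5, 5),
        period=st.floats(2, 60),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_waveform_argmax_sits_at_pi_over_two(self, A, B, period):
        fit = SinusoidFit(frequency=1 / period, A=A, B=B, C=0.3)
        if fit.amplitude < 1e-6:
            return
        t = np.linspace(0, period, 20001)
        theta_max = phase_angle(fit, float(t[np.argmax(fit.predict(t))]))
        theta_min = phase_angle(fit, float(t[np.argmin(fit.predict(t))]))
        res = TWO_PI / 20000 * 2 + 1e-6
        assert min(abs(theta_max - math.pi / 2), abs(theta_max - math.pi / 2 - TWO_PI),
                   abs(theta_max - math.pi / 2 + TWO_PI)) < res
        assert min(abs(theta_min - 3 * math.pi / 2),
                   abs(theta_min - 3 * math.pi / 2 - TWO_PI),
                   abs(theta_min - 3 * math.pi / 2 + TWO_PI)) < res


class TestWindowMapping:
    def test_luteal_example_day_to_angle(self):
        # T = 10, peak at day 2.5 -> days [10/6, 10/3] span 60-120 degrees
        fit = _fit_with_peak_at(10.0, 2.5)
        pw = day_window_to_phase(fit, DayWindow("luteal", 10 / 6, 10 / 3, 10.0))
        assert pw.angle_start == pytest.approx(math.pi / 3, abs=1e-9)
        assert pw.angle_end == pytest.approx(2 * math.pi / 3, abs=1e-9)

    def test_full_cycle_maps_to_full_circle(self):
        fit = _fit_with_peak_at(10.0, 2.5)
        pw = day_window_to_phase(fit, DayWindow("cycle", 0.0, 10.0, 10.0))
        assert pw.length == pytest.approx(TWO_PI)

    def test_angle_to_day_inverse(self):
        fit = _fit_with_peak_at(10.0, 2.5)
        dw = phase_to_day_window(fit, PhaseWindow("luteal", math.pi / 3, 2 * math.pi / 3))
        assert dw.day_start == pytest.approx(10 / 6, abs=1e-9)
        assert dw.day_end == pytest.approx(10 / 3, abs=1e-9)

    def test_mouse_luteal_window_width_is_sixth_of_period(self):
        # 60-degree window on an 11-day cycle peaked at day 5: width 11/6,
        # centred on the progesterone peak
        fit = _fit_with_peak_at(11.0, 5.0)
        dw = phase_to_day_window(fit, PhaseWindow("luteal", math.pi / 3, 2 * math.pi / 3))
        assert dw.width == pytest.approx(11 / 6, abs=1e-9)
        assert 0.5 * (dw.day_start + dw.day_end) == pytest.approx(5.0, abs=1e-9)

    def test_cycle_length_mismatch_warns(self):
        fit = _fit_with_peak_at(10.0, 2.5)
        with pytest.warns(UserWarning):
            day_window_to_phase(fit, DayWindow("w", 1.0, 3.0, 32.0))

    @given(
        period=st.floats(4, 50), peak_day=st.floats(0, 49),
        start=st.floats(0, 0.98), width=st.floats(0.01, 0.9),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_day_angle_day_round_trip(self, period, peak_day, start, width):
        fit = _fit_with_peak_at(period, peak_day % period)
        day_start = start * period
        day_end = min(day_start + width * period, period)
        if day_end - day_start < 1e-6:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dw = DayWindow("w", day_start, day_end, period)
            back = phase_to_day_window(fit, day_window_to_phase(fit, dw))
        assert back.day_start == pytest.approx(day_start, abs=1e-9)
        assert back.day_end == pytest.approx(day_end, abs=1e-9)


class TestAlignSpecies:
    def test_identity_mapping_for_identical_fits(self):
        fit = _fit_with_peak_at(32.0, 20.0)
        dws = [DayWindow("luteal", 16.0, 25.0, 32.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = align_species(fit, dws, fit)
        assert out[0].day_start == pytest.approx(16.0, abs=1e-9)
        assert out[0].day_end == pytest.approx(25.0, abs=1e-9)

    def test_half_period_target_halves_widths(self):
        src = _fit_with_peak_at(32.0, 20.0)
        tgt = _fit_with_peak_at(16.0, 10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = align_species(src, [DayWindow("w", 16.0, 25.0, 32.0)], tgt)
        assert out[0].width == pytest.approx(4.5, abs=1e-9)

    def test_macaque_to_mouse_closed_form(self):
        # source: 32-day cycle peaking at day 20; target: 11-day cycle
        # peaking at day 5.  A window [16, 25] sits at angles
        # 90deg + (d - 20)/32*360deg; target days = 5 + (angle - 90deg)/360deg*11.
        src = _fit_with_peak_at(32.0, 20.0)
        tgt = _fit_with_peak_at(11.0, 5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = align_species(src, [DayWindow("luteal", 16.0, 25.0, 32.0)], tgt)
        expected_start = (5.0 + (16.0 - 20.0) / 32.0 * 11.0) % 11.0  # 3.625
        assert out[0].day_start == pytest.approx(expected_start, abs=1e-9)
        assert out[0].width == pytest.approx(9.0 / 32.0 * 11.0, abs=1e-9)

    def test_round_trip_source_target_source(self):
        src = _fit_with_peak_at(32.0, 20.0)
        tgt = _fit_with_peak_at(11.0, 3.0)
        dws = [
            DayWindow("luteal", 16.0, 25.0, 32.0),
            DayWindow("late_luteal", 25.0, 33.0, 32.0),  # wraps past day 32
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            there = align_species(src, dws, tgt)
            back = align_species(tgt, there, src)
        for dw, b in zip(dws, back):
            assert b.day_start == pytest.approx(dw.day_start, abs=1e-9)
            assert b.day_end == pytest.approx(dw.day_end, abs=1e-9)


class TestWindowContainers:
    def test_wrapped_day_window_splits_at_cycle_boundary(self):
        dw = DayWindow("late_luteal", 25.0, 33.0, 32.0)
        assert dw.split() == [(25.0, 32.0), (0.0, 1.0)]

    def test_in_cycle_window_single_segment(self):
        assert DayWindow("w", 3.0, 7.0, 11.0).split() == [(3.0, 7.0)]

    def test_phase_window_membership_wraps(self):
        pw = PhaseWindow("w", 5.5, 5.5 + 2.0)  # wraps past 2*pi
        assert pw.contains(5.6)
        assert pw.contains(0.5)
        assert not pw.contains(3.0)

    def test_assign_phase_labels_first_match_wins(self):
        w1 = PhaseWindow("luteal", math.pi / 3, 2 * math.pi / 3)
        w2 = PhaseWindow("late_luteal", 2 * math.pi / 3, 7 * math.pi / 6)
        labels = assign_phase_labels([0.1, 1.2, 2.5, 4.0], [w1, w2])
        assert labels == ["other", "luteal", "late_luteal", "other"]

    def test_day_at_angle_inverts_phase_angle(self):
        fit = _fit_with_peak_at(13.0, 4.0)
        for theta in [0.0, 1.0, math.pi, 5.0]:
            d = day_at_angle(fit, theta)
            assert phase_angle(fit, d) == pytest.approx(theta % TWO_PI, abs=1e-9)
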