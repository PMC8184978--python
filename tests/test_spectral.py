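"""Periodograms, harmonic summaries and rhythm-transition events."""

import math

import numpy as np
import pytest

from bdews import (
    CircadianParams,
    TransitionSpec,
    detect_rhythm_transition,
    generate_circadian_series,
    harmonic_summary,
    inject_transition_signature,
    make_windows,
    periodogram,
    rolling_harmonic_ratio,
)
from bdews.spectral import HarmonicSummary

from conftest import make_series

DAY = 1440
WEEK = 7 * DAY


def tone(period, amplitude=1.0, n=WEEK):
    t = np.arange(n, dtype=float)
    return amplitude * np.cos(2 * np.pi * t / period)


class TestPeriodogram:
    def test_pure_tone_concentrates_in_one_bin(self):
        spec = periodogram(tone(DAY))
        k = np.argmax(spec.power)
        assert spec.frequencies[k] == pytest.approx(1 / DAY)
        others = np.delete(spec.power, k)
        assert others.max() < 1e-12 * spec.power[k]

    def test_constant_window_has_no_power(self):
        spec = periodogram(np.full(WEEK, 9.0))
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-16)

    def test_parseval_identity(self, rng):
        x = rng.standard_normal(WEEK)
        spec = periodogram(x)
        assert spec.power.sum() == pytest.approx(WEEK * np.var(x), rel=1e-9)

    def test_invariant_to_additive_constant(self, rng):
        x = rng.standard_normal(WEEK)
        a = periodogram(x)
        b = periodogram(x + 1e4)
        np.testing.assert_allclose(b.power, a.power, atol=1e-6)

    def test_tone_power_scales_with_amplitude_squared(self):
        p1 = harmonic_summary(periodogram(tone(DAY, 1.0))).fundamental_power
        p3 = harmonic_summary(periodogram(tone(DAY, 3.0))).fundamental_power
        assert p3 == pytest.approx(9.0 * p1, rel=1e-9)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            periodogram(np.array([1.0]))


class TestHarmonicSummary:
    def test_pure_24h_tone(self):
        s = harmonic_summary(periodogram(tone(DAY)))
        assert s.ratio == pytest.approx(0.0, abs=1e-12)
        assert s.dominant_period == DAY

    def test_pure_12h_tone_reports_infinite_ratio(self):
        s = harmonic_summary(periodogram(tone(720)))
        assert math.isinf(s.ratio)
        assert s.dominant_period == 720

    def test_equal_amplitude_mixture_gives_unit_ratio(self):
        s = harmonic_summary(periodogram(tone(DAY) + tone(720)))
        assert s.ratio == pytest.approx(1.0, abs=0.01)

    def test_grid_misalignment_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            harmonic_summary(periodogram(np.sin(np.arange(10000.0))))


class TestRollingRatioAndEvents:
    def test_stable_synthetic_patient_keeps_low_ratio(self):
        params = CircadianParams(n_days=30, noise_sd=20.0, seed=3)  # noise <= amplitude/4
        s = generate_circadian_series(params)
        summaries = rolling_harmonic_ratio(make_windows(s))
        assert len(summaries) == 24
        assert max(x.ratio for x in summaries) < 0.5
        assert detect_rhythm_transition(summaries) == []

    def test_180_day_series_yields_174_summaries(self):
        params = CircadianParams(n_days=180, seed=1)
        s = generate_circadian_series(params)
        assert len(rolling_harmonic_ratio(make_windows(s))) == 174

    def test_switch_to_12h_detected_within_a_week_of_the_switch(self):
        params = CircadianParams(n_days=75, seed=5)
        s = generate_circadian_series(params)
        spec = TransitionSpec(onset_day=69, ramp_days=1, variance_gain=1.0,
                              rhythm_switch_period=720, switch_day=60)
        out = inject_transition_signature(s, spec, params)
        events = detect_rhythm_transition(rolling_harmonic_ratio(make_windows(out)))
        switch = [e for e in events if e.kind == "SWITCH"]
        assert switch and 60 <= switch[0].end_day <= 67
        assert switch[0].dominant_period == 720

    def test_switch_to_4h_detected(self):
        params = CircadianParams(n_days=40, seed=5)
        s = generate_circadian_series(params)
        spec = TransitionSpec(onset_day=35, ramp_days=1, variance_gain=1.0,
                              rhythm_switch_period=240, switch_day=30)
        out = inject_transition_signature(s, spec, params)
        events = detect_rhythm_transition(rolling_harmonic_ratio(make_windows(out)))
        switch = [e for e in events if e.kind == "SWITCH"]
        assert switch and switch[0].dominant_period == 240

    def test_threshold_crossings_on_a_synthetic_ratio_series(self):
        ratios = [0.1, 0.2, 0.98, 1.3]
        summaries = [
            HarmonicSummary(
                fundamental_period=DAY,
                fundamental_power=1.0,
                harmonic_powers={1: 1.0, 2: r},
                ratio=r,
                dominant_period=DAY if r <= 1 else 720,
                window_end_day=i,
            )
            for i, r in enumerate(ratios)
        ]
        events = detect_rhythm_transition(summaries)
        assert [(e.kind, e.end_day) for e in events] == [("WARN", 2), ("SWITCH", 3)]

    def test_warn_is_monotone_in_threshold(self):
        params = CircadianParams(n_days=40, seed=5)
        s = generate_circadian_series(params)
        spec = TransitionSpec(onset_day=35, ramp_days=1, variance_gain=1.0,
                              rhythm_switch_period=720, switch_day=25)
        out = inject_transition_signature(s, spec, params)
        summaries = rolling_harmonic_ratio(make_windows(out))

        def warn_day(th):
            ev = [e for e in detect_rhythm_transition(summaries, warn_threshold=th)
                  if e.kind == "WARN"]
            return ev[0].end_day if ev else np.inf

        assert warn_day(0.5) <= warn_day(0.9) <= warn_day(1.5)

    def test_missing_epochs_are_mean_filled_not_fatal(self, rng):
        counts = tone(DAY, 50.0) + 100.0
        mask = np.ones(WEEK, dtype=bool)
        mask[rng.choice(WEEK, size=500, replace=False)] = False
        s = make_series(counts, mask=mask)
        summaries = rolling_harmonic_ratio(make_windows(s))
        assert summaries[0].dominant_period == DAY
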