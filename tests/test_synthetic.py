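"""Synthetic generator: determinism, rhythm structure, injected signatures."""

import numpy as np
import pytest

from bdews import (
    CircadianParams,
    TransitionSpec,
    detect_episode_onset,
    generate_circadian_series,
    generate_symptom_series,
    inject_transition_signature,
)
from bdews.indicators import window_variance
from bdews.spectral import harmonic_summary, periodogram


class TestCircadianGenerator:
    def test_seeded_determinism(self, quiet_params):
        a = generate_circadian_series(quiet_params)
        b = generate_circadian_series(quiet_params)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_noiseless_series_is_a_pure_1440_tone(self):
        p = CircadianParams(n_days=14, mesor=100, amplitude=50, noise_sd=0, seed=0)
        s = generate_circadian_series(p)
        for start in (0, 5 * 1440):
            spec = periodogram(s.counts[start : start + 7 * 1440])
            peak = np.argmax(spec.power[1:]) + 1
            assert spec.frequencies[peak] == pytest.approx(1 / 1440)

    def test_degenerate_flat_series(self):
        p = CircadianParams(n_days=8, mesor=42.0, amplitude=0, noise_sd=0)
        s = generate_circadian_series(p)
        np.testing.assert_array_equal(s.counts, 42.0)

    def test_counts_non_negative(self, quiet_series):
        assert (quiet_series.counts >= 0).all()

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="n_days"):
            CircadianParams(n_days=5)


class TestInjectTransition:
    def test_unit_gain_without_switch_is_identity(self, quiet_series, quiet_params):
        spec = TransitionSpec(onset_day=10, ramp_days=5, variance_gain=1.0)
        out = inject_transition_signature(quiet_series, spec, quiet_params)
        np.testing.assert_array_equal(out.counts, quiet_series.counts)

    def test_pre_ramp_counts_bit_identical(self, quiet_series, quiet_params):
        spec = TransitionSpec(onset_day=10, ramp_days=5, variance_gain=4.0)
        out = inject_transition_signature(quiet_series, spec, quiet_params)
        cut = 5 * 1440
        np.testing.assert_array_equal(out.counts[:cut], quiet_series.counts[:cut])
        assert (out.counts >= 0).all()

    def test_variance_ramp_raises_late_window_variance(self):
        """Monte-Carlo: mean last-pre-onset-day variance exceeds pre-ramp variance."""
        pre, late = [], []
        for seed in range(100):
            params = CircadianParams(n_days=30, seed=seed)
            s = generate_circadian_series(params)
            spec = TransitionSpec(onset_day=29, ramp_days=28, variance_gain=4.0)
            out = inject_transition_signature(s, spec, params)
            day = 1440
            pre.append(window_variance(out.counts[0:day]))          # ramp starts day 1
            late.append(window_variance(out.counts[28 * day : 29 * day]))
        assert np.mean(late) > np.mean(pre)

    def test_rhythm_switch_flips_harmonic_ratio(self, quiet_params):
        params = CircadianParams(n_days=21, seed=11)
        s = generate_circadian_series(params)
        spec = TransitionSpec(
            onset_day=14, ramp_days=1, variance_gain=1.0,
            rhythm_switch_period=720, switch_day=10,
        )
        out = inject_transition_signature(s, spec, params)
        pre = harmonic_summary(periodogram(out.counts[: 7 * 1440]))
        post = harmonic_summary(periodogram(out.counts[14 * 1440 :]))
        assert pre.ratio < 1
        assert post.ratio > 1

    def test_ramp_before_day_zero_rejected(self):
        with pytest.raises(ValueError, match="ramp"):
            TransitionSpec(onset_day=5, ramp_days=10)


class TestSymptomGenerator:
    def test_manic_series_round_trips_onset(self):
        spec = TransitionSpec(onset_day=70, episode_type="manic")
        q = generate_symptom_series(20, spec, seed=5)
        onset = detect_episode_onset(q)
        assert onset.episode_type == "manic"
        assert onset.onset_week_index == 10

    def test_depressive_series_round_trips_onset(self):
        spec = TransitionSpec(onset_day=70, episode_type="depressive")
        q = generate_symptom_series(20, spec, seed=5)
        onset = detect_episode_onset(q)
        assert onset.episode_type == "depressive"
        assert onset.onset_week_index == 10

    def test_null_series_never_qualifies(self):
        for seed in range(20):
            q = generate_symptom_series(26, None, seed=seed)
            assert detect_episode_onset(q) is None

    def test_seeded_determinism(self):
        a = generate_symptom_series(12, None, seed=9)
        b = generate_symptom_series(12, None, seed=9)
        np.testing.assert_array_equal(a.asrm, b.asrm)
        np.testing.assert_array_equal(a.ids_sr, b.ids_sr)

    def test_onset_must_fit(self):
        with pytest.raises(ValueError, match="does not leave room"):
            generate_symptom_series(10, TransitionSpec(onset_day=65, episode_type="manic"))
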