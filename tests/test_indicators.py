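"""Per-window early-warning indicators and mean-activity comparisons."""

import numpy as np
import pytest

from bdews import (
    acf_at_lag,
    compare_mean_activity,
    make_windows,
    rolling_ews,
    window_kurtosis,
    window_variance,
)
from bdews.datasets import reported_mean_activity

from conftest import make_series

DAY = 1440


class TestVariance:
    def test_hand_computed_value(self):
        assert window_variance(np.array([1.0, 2, 3, 4])) == pytest.approx(5 / 3)

    def test_constant_window_is_zero(self):
        assert window_variance(np.full(100, 7.0)) == 0.0

    def test_quadratic_scaling(self, rng):
        x = rng.random(500)
        assert window_variance(2 * x) == pytest.approx(4 * window_variance(x))

    def test_too_few_valid_values(self):
        assert np.isnan(window_variance(np.array([1.0])))


class TestKurtosis:
    def test_hand_computed_moments(self):
        # m2 = 0.1875, m4 = 0.08203125 -> m4/m2^2 = 2.333...
        assert window_kurtosis(np.array([0.0, 0, 0, 1])) == pytest.approx(7 / 3)

    def test_two_point_mass_attains_pearson_lower_bound(self):
        assert window_kurtosis(np.array([-1.0, 1, -1, 1])) == pytest.approx(1.0)

    def test_gaussian_sample_near_three(self, rng):
        x = rng.standard_normal(10080)
        assert window_kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_zero_variance_undefined(self):
        assert np.isnan(window_kurtosis(np.full(10, 3.0)))


class TestAcfAtLag:
    def setup_method(self):
        t = np.arange(7 * DAY, dtype=float)
        self.sin_1440 = np.sin(2 * np.pi * t / DAY)
        self.sin_720 = np.sin(2 * np.pi * t / 720.0)

    def test_half_period_lag_is_antiphase(self):
        assert acf_at_lag(self.sin_1440, 720) == pytest.approx(-1.0, abs=0.01)

    def test_full_period_lag_is_in_phase(self):
        assert acf_at_lag(self.sin_1440, 1440) == pytest.approx(1.0, abs=0.01)

    def test_deregulated_12h_rhythm_is_in_phase_at_720(self):
        # a 12-h rhythm turns the day/night contrast statistic positive
        assert acf_at_lag(self.sin_720, 720) == pytest.approx(1.0, abs=0.01)

    def test_bounds_on_random_input(self, rng):
        for _ in range(20):
            x = rng.standard_normal(300)
            assert -1.0 <= acf_at_lag(x, 17) <= 1.0

    def test_zero_variance_undefined(self):
        assert np.isnan(acf_at_lag(np.full(100, 2.0), 10))

    def test_invalid_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            acf_at_lag(np.arange(10.0), 10)


class TestMaskedComputation:
    """Deleting invalid epochs must equal the masked computation (variance/kurtosis)."""

    def test_masked_equals_deleted(self, rng):
        x = rng.random(2000)
        mask = rng.random(2000) > 0.2
        assert window_variance(x, mask) == pytest.approx(window_variance(x[mask]))
        assert window_kurtosis(x, mask) == pytest.approx(window_kurtosis(x[mask]))


class TestRollingEws:
    def test_series_lengths_match_window_count(self, rng):
        s = make_series(rng.random(30 * DAY))
        ews = rolling_ews(make_windows(s))
        for name in ("variance", "kurtosis", "acf720"):
            assert ews[name].values.size == 24

    def test_constant_series(self):
        s = make_series(np.full(8 * DAY, 5.0))
        ews = rolling_ews(make_windows(s))
        np.testing.assert_array_equal(ews["variance"].values, 0.0)
        assert np.isnan(ews["kurtosis"].values).all()
        assert np.isnan(ews["acf720"].values).all()

    def test_affine_invariance_of_kurtosis_and_acf(self, rng):
        x = rng.random(9 * DAY)
        a = rolling_ews(make_windows(make_series(x)))
        b = rolling_ews(make_windows(make_series(3.0 * x + 11.0)))
        np.testing.assert_allclose(b["kurtosis"].values, a["kurtosis"].values, rtol=1e-9)
        np.testing.assert_allclose(b["acf720"].values, a["acf720"].values, rtol=1e-9)

    def test_unusable_windows_yield_missing(self, rng):
        counts = rng.random(9 * DAY)
        mask = np.ones(9 * DAY, dtype=bool)
        mask[: 2 * DAY] = False  # first window 5/7 complete, second 6/7
        s = make_series(counts, mask=mask)
        ews = rolling_ews(make_windows(s))
        assert np.isnan(ews["variance"].values[0])
        assert np.isnan(ews["variance"].values[1])
        assert np.isfinite(ews["variance"].values[2])


class TestMeanActivity:
    @pytest.mark.parametrize("period", ["pre_onset", "during"])
    def test_reproduces_published_labels(self, period):
        """The published euthymic-vs-comparison means map to their printed labels."""
        table = reported_mean_activity(period)
        for row in table.itertuples():
            cmp = compare_mean_activity(row.euthymic_mean, row.comparison_mean)
            assert cmp.label == row.label

    def test_equal_means(self):
        assert compare_mean_activity(5.0, 5.0).label == "equal"

    def test_undefined_mean_rejected(self):
        with pytest.raises(ValueError):
            compare_mean_activity(np.nan, 1.0)
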