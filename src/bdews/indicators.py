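"""Per-window early-warning indicators and mean-activity comparisons.

Three indicators are computed on each usable 7-day window of the detrended
minute series:

* ``variance`` — sample variance (denominator n − 1);
* ``kurtosis`` — raw Pearson kurtosis m4/m2² (central moments with
  denominator n; 3 for a Gaussian, lower bound 1), *not* excess kurtosis —
  the shift between the two conventions is monotone and cannot change a
  trend test;
* ``acf720`` — autocorrelation at a 12-h lag, the day/night contrast
  statistic: near −1 for a strong 24-h rhythm, drifting toward 0 or positive
  values as the rest/activity rhythm deregulates.

The acf estimator centres on the full-window mean and normalizes the mean
pairwise cross-product by the mean squared deviation, so a pure 1440-min
sinusoid scores −1 at lag 720 and +1 at lag 1440 regardless of the partial
final cycle; under missingness only pairs with both epochs valid enter the
numerator.  Results are clipped to [−1, 1].

Mean-activity comparisons (euthymic reference week vs the week before — or
the first week of — an episode) are taken on raw, not detrended, counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MINUTES_PER_DAY, ActivitySeries
from .preprocess import WindowedSeries

__all__ = [
    "EWSSeries",
    "MeanActivityComparison",
    "window_variance",
    "window_kurtosis",
    "acf_at_lag",
    "rolling_ews",
    "interval_mean",
    "compare_mean_activity",
    "INDICATORS",
]

#: Canonical indicator order used throughout reports.
INDICATORS = ("variance", "kurtosis", "acf720")

DEFAULT_ACF_LAG = 720


@dataclass
class EWSSeries:
    """Daily values of one indicator, aligned to window end days."""

    indicator: str
    end_days: np.ndarray
    values: np.ndarray
    lag: int | None = None

    def __post_init__(self) -> None:
        self.end_days = np.asarray(self.end_days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.end_days.shape != self.values.shape:
            raise ValueError("end_days and values must have equal length")

    @property
    def mask(self) -> np.ndarray:
        """Usable flags: True where the indicator is defined."""
        return np.isfinite(self.values)

    def restrict_days(self, start_day: int, stop_day: int) -> "EWSSeries":
        """Values whose window end day lies in the half-open [start_day, stop_day)."""
        keep = (self.end_days >= start_day) & (self.end_days < stop_day)
        return EWSSeries(self.indicator, self.end_days[keep], self.values[keep], lag=self.lag)


@dataclass
class MeanActivityComparison:
    """Raw-count mean of a target week against a euthymic reference week."""

    reference_mean: float
    target_mean: float
    label: str  # "more" | "less" | "equal"


def window_variance(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sample variance (n − 1) over valid epochs; NaN with < 2 valid values."""
    v = _valid(values, mask)
    if v.size < 2:
        return np.nan
    return float(np.var(v, ddof=1))


def window_kurtosis(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Raw Pearson kurtosis m4/m2²; NaN with < 4 valid values or zero variance."""
    v = _valid(values, mask)
    if v.size < 4:
        return np.nan
    d = v - v.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return np.nan
    return float(np.mean(d**4) / m2**2)


def acf_at_lag(values: np.ndarray, lag: int, mask: np.ndarray | None = None) -> float:
    """Autocorrelation at ``lag`` epochs; NaN with < 2 valid pairs or zero variance."""
    x = np.asarray(values, dtype=float)
    if not 0 < lag < x.size:
        raise ValueError("lag must satisfy 0 < lag < window length")
    m = np.isfinite(x) if mask is None else np.asarray(mask, dtype=bool)
    valid_x = x[m]
    if valid_x.size < 2:
        return np.nan
    xbar = valid_x.mean()
    den = np.mean((valid_x - xbar) ** 2)
    if den == 0.0:
        return np.nan
    pair = m[:-lag] & m[lag:]
    if int(pair.sum()) < 2:
        return np.nan
    a = x[:-lag][pair] - xbar
    b = x[lag:][pair] - xbar
    r = float(np.mean(a * b) / den)
    return float(np.clip(r, -1.0, 1.0))


def rolling_ews(windowed: WindowedSeries, lag: int = DEFAULT_ACF_LAG) -> dict[str, EWSSeries]:
    """All three indicators over every window; unusable windows yield NaN.

    Returns a dict keyed by :data:`INDICATORS`.  Raises if no window is
    usable.
    """
    if not windowed.usable_windows():
        raise ValueError("no usable windows (all below the completeness threshold)")
    end_days = windowed.end_days
    var = np.full(windowed.n_windows, np.nan)
    kurt = np.full(windowed.n_windows, np.nan)
    acf = np.full(windowed.n_windows, np.nan)
    for i, w in enumerate(windowed):
        if not w.usable:
            continue
        var[i] = window_variance(w.values, w.mask)
        kurt[i] = window_kurtosis(w.values, w.mask)
        acf[i] = acf_at_lag(w.values, lag, w.mask)
    return {
        "variance": EWSSeries("variance", end_days, var),
        "kurtosis": EWSSeries("kurtosis", end_days, kurt),
        "acf720": EWSSeries("acf720", end_days, acf, lag=lag),
    }


def interval_mean(series: ActivitySeries, start_day: float, stop_day: float) -> float:
    """Mean raw count over valid epochs in days ``[start_day, stop_day)``."""
    lo = int(round(start_day * MINUTES_PER_DAY))
    hi = int(round(stop_day * MINUTES_PER_DAY))
    hi = min(hi, series.n_epochs)
    if hi <= lo:
        raise ValueError("empty day interval")
    sl = slice(lo, hi)
    v = series.counts[sl][series.valid_mask[sl]]
    if v.size == 0:
        raise ValueError("no valid epochs in interval")
    return float(v.mean())


def compare_mean_activity(reference_mean: float, target_mean: float) -> MeanActivityComparison:
    """Label the target week as more / less / equal activity vs the reference week."""
    if not (np.isfinite(reference_mean) and np.isfinite(target_mean)):
        raise ValueError("both means must be defined")
    if target_mean > reference_mean:
        label = "more"
    elif target_mean < reference_mean:
        label = "less"
    else:
        label = "equal"
    return MeanActivityComparison(reference_mean, target_mean, label)


def _valid(values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if mask is None:
        return x[np.isfinite(x)]
    return x[np.asarray(mask, dtype=bool)]
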