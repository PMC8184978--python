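"""Detrending and rolling 7-day / 1-day-step windowing of minute-level series.

Rolling-window early-warning indicators are sensitive to slow drifts, so the
full series is first reduced to residuals from its ordinary-least-squares
line (fitted on valid epochs, time in minutes as regressor).  The detrended
series is then cut into overlapping windows — 7 days long, stepped by 1 day,
only full windows emitted — which every indicator downstream shares.  A
7-day window always contains a full weekend, levelling weekday/weekend
contrast across windows.

Windows are labelled by the day on which they *end*, so the indicator value
dated day ``d`` uses only epochs observed strictly before day ``d``; a
four-week pre-onset span therefore yields 28 daily indicator values.
Day indices are 0-based and intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MINUTES_PER_DAY, ActivitySeries

__all__ = ["WindowSpec", "Window", "WindowedSeries", "detrend_linear", "make_windows"]


@dataclass(frozen=True)
class WindowSpec:
    """Rolling-window geometry and completeness rule.

    window_length and step are in minutes (defaults: 7 days / 1 day);
    windows whose valid-epoch fraction falls below ``min_completeness``
    are emitted but flagged unusable.
    """

    window_length: int = 7 * MINUTES_PER_DAY
    step: int = MINUTES_PER_DAY
    min_completeness: float = 0.9

    def __post_init__(self) -> None:
        if not (self.window_length >= self.step >= 1):
            raise ValueError("need window_length >= step >= 1 minute")
        if self.window_length % self.step:
            raise ValueError("window_length must be a multiple of step")
        if not 0.0 <= self.min_completeness <= 1.0:
            raise ValueError("min_completeness must lie in [0, 1]")


@dataclass
class Window:
    """One rolling window: epochs ``[start_epoch, start_epoch + len)`` of the source."""

    index: int
    end_day: int
    start_epoch: int
    values: np.ndarray
    mask: np.ndarray
    usable: bool


@dataclass
class WindowedSeries:
    """Ordered full windows over a (typically detrended) activity series."""

    windows: list[Window]
    source: ActivitySeries
    spec: WindowSpec

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def end_days(self) -> np.ndarray:
        return np.array([w.end_day for w in self.windows], dtype=int)

    def usable_windows(self) -> list[Window]:
        return [w for w in self.windows if w.usable]

    def __iter__(self):
        return iter(self.windows)


def detrend_linear(series: ActivitySeries) -> ActivitySeries:
    """Subtract the OLS regression line fitted on valid epochs.

    The residual series keeps the original missingness mask; residuals may
    be negative.  Fitting on residuals again returns (numerically) the same
    series, and adding a constant to the input does not change the output.
    """
    valid = series.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cannot detrend an all-missing series")
    if n_valid < 2:
        raise ValueError("detrending needs at least 2 valid epochs")
    t = np.arange(series.n_epochs, dtype=float)
    slope, intercept = np.polyfit(t[valid], series.counts[valid], deg=1)
    residuals = series.counts - (slope * t + intercept)
    return series.with_counts(residuals)


def make_windows(series: ActivitySeries, spec: WindowSpec | None = None) -> WindowedSeries:
    """Cut the series into rolling windows per ``spec``.

    Only full windows are produced: a D-day series yields D − 6 windows at
    the 7-day/1-day defaults, with end-day labels 7, 8, …, D.
    """
    spec = spec or WindowSpec()
    n = series.n_epochs
    if n < spec.window_length:
        raise ValueError(
            f"series of {n} epochs is shorter than one window ({spec.window_length} epochs)"
        )
    n_windows = (n - spec.window_length) // spec.step + 1
    windows = []
    for k in range(n_windows):
        start = k * spec.step
        stop = start + spec.window_length
        mask = series.valid_mask[start:stop]
        completeness = float(mask.mean())
        windows.append(
            Window(
                index=k,
                end_day=stop // MINUTES_PER_DAY,
                start_epoch=start,
                values=series.counts[start:stop],
                mask=mask,
                usable=completeness >= spec.min_completeness,
            )
        )
    return WindowedSeries(windows=windows, source=series, spec=spec)
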