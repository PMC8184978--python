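"""Unsmoothed FFT periodograms, harmonic ratios, and rhythm-transition events.

Each rolling 7-day window of the *raw* count series (mean-removed, no taper,
no smoothing) yields a one-sided periodogram on the natural grid k/N cycles
per minute.  Because the window length (10080 min) is an exact multiple of
the fundamental period (1440 min = 24 h), the fundamental and its harmonics
n/1440 for n = 2..6 fall exactly on bins, so their powers can be read off
without leakage.

The harmonic ratio — power at the second harmonic (12-h bin) divided by
power at the fundamental (24-h bin) — tracks the displacement of the normal
24-h rest/activity rhythm by an atypical 12-h rhythm: values approaching 1
warn of an upcoming rhythm change, and a dominant period other than 1440 min
marks the change itself.  Candidate dominant periods are restricted to
1440/n for n = 1..6, covering the observed 12-h and 4-h phenomena while
avoiding leakage-driven spurious dominants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MINUTES_PER_DAY
from .preprocess import WindowedSeries

__all__ = [
    "Spectrum",
    "HarmonicSummary",
    "RhythmEvent",
    "periodogram",
    "harmonic_summary",
    "rolling_harmonic_ratio",
    "detect_rhythm_transition",
]

FUNDAMENTAL_PERIOD = float(MINUTES_PER_DAY)  # 24 h in minutes
N_HARMONICS = 6

#: Fundamental power below this fraction of total power is treated as absent
#: and the ratio reported as +inf.
_FUNDAMENTAL_EPS = 1e-12


@dataclass
class Spectrum:
    """One-sided periodogram: frequencies in cycles/min, power in count-units²."""

    frequencies: np.ndarray
    power: np.ndarray
    window_end_day: int | None = None


@dataclass
class HarmonicSummary:
    """Fundamental/harmonic powers, their ratio and the dominant period for one window."""

    fundamental_period: float
    fundamental_power: float
    harmonic_powers: dict[int, float]
    ratio: float
    dominant_period: float
    window_end_day: int | None = None


@dataclass
class RhythmEvent:
    kind: str  # "WARN" | "SWITCH"
    end_day: int | None
    ratio: float
    dominant_period: float


def periodogram(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    window_end_day: int | None = None,
) -> Spectrum:
    """Mean-removed, unsmoothed one-sided periodogram of one window.

    Missing epochs are filled with the window mean before the FFT (a plain
    periodogram cannot mask).  Ordinates are scaled so their sum equals
    N × (sample variance with denominator N) — the Parseval identity.
    """
    x = np.asarray(values, dtype=float).copy()
    n = x.size
    if n < 2:
        raise ValueError("periodogram needs a window of at least 2 epochs")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if not m.any():
            raise ValueError("window has no valid epochs")
        x[~m] = x[m].mean()
    x -= x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0)
    return Spectrum(frequencies=freqs, power=spec, window_end_day=window_end_day)


def harmonic_summary(
    spectrum: Spectrum,
    fundamental_period: float = FUNDAMENTAL_PERIOD,
    n_harmonics: int = N_HARMONICS,
) -> HarmonicSummary:
    """Read fundamental and harmonic powers off the grid and form their ratio.

    The harmonic frequencies are n / fundamental_period for n = 1..6; the
    window length must be an exact multiple of the fundamental period so
    these lie on the frequency grid.  The ratio divides the second-harmonic
    (12-h) power by the fundamental (24-h) power; a vanishing fundamental
    yields +inf.
    """
    if len(spectrum.frequencies) < 2:
        raise ValueError("spectrum too short for harmonic analysis")
    df = float(spectrum.frequencies[1] - spectrum.frequencies[0])
    k0_f = 1.0 / (fundamental_period * df)
    k0 = round(k0_f)
    if k0 < 1 or abs(k0_f - k0) > 1e-9:
        raise ValueError(
            "fundamental frequency is off the grid: use a window length that is "
            f"an integer multiple of {fundamental_period:g} minutes"
        )
    n_h = min(n_harmonics, (len(spectrum.power) - 1) // k0)
    if n_h < 2:
        raise ValueError("window too short to resolve the second harmonic")
    powers = {n: float(spectrum.power[n * k0]) for n in range(1, n_h + 1)}
    fundamental = powers[1]
    total = float(spectrum.power.sum())
    if fundamental < _FUNDAMENTAL_EPS * total:
        ratio = math.inf
    else:
        ratio = powers[2] / fundamental
    dominant_n = max(powers, key=lambda n: (powers[n], -n))
    return HarmonicSummary(
        fundamental_period=fundamental_period,
        fundamental_power=fundamental,
        harmonic_powers=powers,
        ratio=ratio,
        dominant_period=fundamental_period / dominant_n,
        window_end_day=spectrum.window_end_day,
    )


def rolling_harmonic_ratio(
    windowed: WindowedSeries,
    fundamental_period: float = FUNDAMENTAL_PERIOD,
) -> list[HarmonicSummary]:
    """One harmonic summary per usable window, labelled by window end day."""
    usable = windowed.usable_windows()
    if not usable:
        raise ValueError("no usable windows")
    return [
        harmonic_summary(
            periodogram(w.values, w.mask, window_end_day=w.end_day),
            fundamental_period=fundamental_period,
        )
        for w in usable
    ]


def detect_rhythm_transition(
    summaries: list[HarmonicSummary],
    warn_threshold: float = 0.9,
    switch_threshold: float = 1.0,
) -> list[RhythmEvent]:
    """Threshold the harmonic-ratio series into WARN and SWITCH events.

    A WARN is emitted at the first summary whose ratio reaches
    ``warn_threshold``; a SWITCH at the first summary whose dominant period
    leaves the fundamental (any of its harmonics counts, covering 12-h and
    4-h rhythm changes) or whose ratio reaches ``switch_threshold``.
    Raising a threshold can only delay or suppress the matching event.
    """
    if not summaries:
        raise ValueError("need at least one harmonic summary")
    events: list[RhythmEvent] = []
    for s in summaries:
        if s.ratio >= warn_threshold:
            events.append(RhythmEvent("WARN", s.window_end_day, s.ratio, s.dominant_period))
            break
    for s in summaries:
        if s.dominant_period != s.fundamental_period or s.ratio >= switch_threshold:
            events.append(RhythmEvent("SWITCH", s.window_end_day, s.ratio, s.dominant_period))
            break
    events.sort(key=lambda e: (e.end_day if e.end_day is not None else -1, e.kind != "WARN"))
    return events
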