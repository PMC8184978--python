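"""Synthetic actigraphy and weekly-symptom generators.

Patients in the motivating study wore a wrist actigraph continuously for
about 180 days at 1-minute epochs while filling in weekly ASRM / IDS-SR
questionnaires.  No raw recordings are distributed, so this module generates
series with the statistical structure the analysis assumes:

* a cosinor (mesor + 24-h cosine) mean activity curve with truncated-at-zero
  Gaussian epoch noise, giving a dominant 1440-min spectral period,
  day/night contrast and heteroscedastic non-negative counts;
* injectable pre-transition signatures — a linear ramp of the epoch noise
  scale toward ``variance_gain`` × baseline at episode onset, and an optional
  switch of the rhythmic component to a shorter period (e.g. 720 min, the
  atypical 12-h rhythm) from ``switch_day`` onward;
* weekly symptom series that cross (or, for null patients, never cross) the
  episode criteria: ASRM > 5 for ≥ 2 consecutive weeks (manic), IDS-SR > 25
  for ≥ 3 consecutive weeks (depressive).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MINUTES_PER_DAY, ActivitySeries, QuestionnaireSeries

__all__ = [
    "CircadianParams",
    "TransitionSpec",
    "generate_circadian_series",
    "inject_transition_signature",
    "generate_symptom_series",
    "simulate_patient",
]

#: Default first day of a simulated recording (a Monday; weekly
#: questionnaires are aligned to it).
DEFAULT_START = pd.Timestamp("2020-01-06 00:00:00")


@dataclass
class CircadianParams:
    """Parameters of the baseline circadian activity model.

    Defaults mimic the study conditions: ~180 days of recording with daytime
    activity on the order of 100-200 MotionWatch counts/min (the range of the
    published per-patient euthymic means) and near-zero counts at night.

    Parameters
    ----------
    n_days
        Length of the recording, days (study recordings ran ~180 days).
    mesor
        Rhythm-adjusted mean of the cosinor curve, counts/min.
    amplitude
        Peak deviation of the 24-h cosine from the mesor, counts/min.  The
        default trough ``mesor - amplitude = 20`` leaves genuinely low night
        activity that the zero-truncation occasionally clips, as real
        night-time wrist data do.
    noise_sd
        Standard deviation of the Gaussian epoch noise, counts/min.
    acrophase_minute
        Minute-of-day of the activity peak (default 15:00).
    clip_at_zero
        Truncate counts at zero (device counts are non-negative).
    seed
        Seed for the generator's own randomness.
    """

    n_days: int = 180
    mesor: float = 100.0
    amplitude: float = 80.0
    noise_sd: float = 20.0
    acrophase_minute: float = 900.0
    clip_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 8:
            raise ValueError("n_days must be >= 8 (one full analysis window plus a step)")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


@dataclass
class TransitionSpec:
    """Pre-transition signature to embed in a synthetic recording.

    The epoch noise scale ramps linearly from its baseline at
    ``onset_day - ramp_days`` to ``variance_gain`` × baseline at
    ``onset_day`` (and stays there), emulating the rising-variance /
    rising-kurtosis signature expected before a tipping point.  If
    ``rhythm_switch_period`` is set, the periodic component switches from
    1440 min to that period at ``switch_day`` (same amplitude), emulating
    the observed collapse of the 24-h rest/activity rhythm into an atypical
    12-h (or shorter) rhythm.
    """

    onset_day: int
    ramp_days: int = 28
    variance_gain: float = 4.0
    rhythm_switch_period: float | None = None
    switch_day: int | None = None
    episode_type: str = "depressive"

    def __post_init__(self) -> None:
        if not 0 < self.ramp_days <= self.onset_day:
            raise ValueError("need 0 < ramp_days <= onset_day (ramp may not precede day 0)")
        if self.variance_gain <= 0:
            raise ValueError("variance_gain must be positive")
        if self.rhythm_switch_period is not None:
            if self.switch_day is None:
                raise ValueError("rhythm_switch_period requires switch_day")
            if self.rhythm_switch_period <= 0:
                raise ValueError("rhythm_switch_period must be positive")
        if self.episode_type not in ("manic", "depressive"):
            raise ValueError("episode_type must be 'manic' or 'depressive'")

    @property
    def onset_week(self) -> int:
        return self.onset_day // 7


def _cosine_mean(params: CircadianParams, n_epochs: int, period: float = float(MINUTES_PER_DAY)) -> np.ndarray:
    t = np.arange(n_epochs, dtype=float)
    return params.mesor + params.amplitude * np.cos(
        2.0 * np.pi * (t - params.acrophase_minute) / period
    )


def generate_circadian_series(
    params: CircadianParams,
    patient_id: str = "sim",
    start_time: pd.Timestamp = DEFAULT_START,
) -> ActivitySeries:
    """Generate a baseline (euthymic) 1-min actigraphy series.

    The result has ``n_days * 1440`` epochs, non-negative counts, and — for
    ``amplitude > 0`` — its dominant nonzero spectral period at 1440 min.
    """
    n_epochs = params.n_days * MINUTES_PER_DAY
    rng = np.random.default_rng(params.seed)
    counts = _cosine_mean(params, n_epochs)
    if params.noise_sd > 0:
        counts = counts + rng.normal(0.0, params.noise_sd, size=n_epochs)
    if params.clip_at_zero:
        counts = np.maximum(counts, 0.0)
    return ActivitySeries(patient_id=patient_id, start_time=start_time, counts=counts)


def inject_transition_signature(
    series: ActivitySeries,
    spec: TransitionSpec,
    params: CircadianParams,
) -> ActivitySeries:
    """Embed a pre-transition signature into a generated series.

    ``params`` must be the parameters the series was generated with: the
    deterministic cosinor mean curve is reconstructed from them, the epoch
    residuals are rescaled by the linear variance ramp, and (optionally) the
    periodic component is swapped to ``rhythm_switch_period`` after
    ``switch_day``.  Epochs before both the ramp and the switch are returned
    bit-identical; output counts remain non-negative.
    """
    n_epochs = series.n_epochs
    if spec.onset_day * MINUTES_PER_DAY > n_epochs:
        raise ValueError("onset_day lies beyond the end of the series")
    if spec.switch_day is not None and spec.switch_day * MINUTES_PER_DAY > n_epochs:
        raise ValueError("switch_day lies beyond the end of the series")

    t = np.arange(n_epochs)
    onset_epoch = spec.onset_day * MINUTES_PER_DAY
    ramp_start = (spec.onset_day - spec.ramp_days) * MINUTES_PER_DAY

    gain = np.ones(n_epochs)
    in_ramp = (t >= ramp_start) & (t < onset_epoch)
    gain[in_ramp] = 1.0 + (spec.variance_gain - 1.0) * (t[in_ramp] - ramp_start) / (
        onset_epoch - ramp_start
    )
    gain[t >= onset_epoch] = spec.variance_gain

    base = _cosine_mean(params, n_epochs)
    mean_out = base.copy()
    switched = np.zeros(n_epochs, dtype=bool)
    if spec.rhythm_switch_period is not None:
        switched = t >= spec.switch_day * MINUTES_PER_DAY
        alt = _cosine_mean(params, n_epochs, period=float(spec.rhythm_switch_period))
        mean_out[switched] = alt[switched]

    # touch only epochs the signature actually modifies, so the pre-ramp
    # segment stays bit-identical to the input
    modified = (gain != 1.0) | switched
    out = series.counts.copy()
    out[modified] = mean_out[modified] + gain[modified] * (
        series.counts[modified] - base[modified]
    )
    if params.clip_at_zero:
        out[modified] = np.maximum(out[modified], 0.0)
    return series.with_counts(out)


def generate_symptom_series(
    n_weeks: int,
    episode: TransitionSpec | None = None,
    seed: int = 0,
    patient_id: str = "sim",
    start_date: pd.Timestamp = DEFAULT_START,
) -> QuestionnaireSeries:
    """Generate weekly ASRM / IDS-SR scores, optionally crossing an episode criterion.

    With a manic ``episode``, ASRM exceeds 5 for at least two consecutive
    weeks starting at the onset week and never before; with a depressive one,
    IDS-SR exceeds 25 for at least three consecutive weeks starting at the
    onset week and never before.  With ``episode=None`` neither criterion is
    ever satisfied (a euthymic "null" patient).
    """
    if n_weeks < 2:
        raise ValueError("need at least 2 weeks of symptom data")
    rng = np.random.default_rng(seed)
    # euthymic baselines: strictly below both episode thresholds
    asrm = rng.integers(0, 5, size=n_weeks).astype(float)
    ids = rng.integers(8, 21, size=n_weeks).astype(float)

    if episode is not None:
        week = episode.onset_week
        min_run = 2 if episode.episode_type == "manic" else 3
        if week + min_run > n_weeks:
            raise ValueError(
                f"{episode.episode_type} onset at week {week} does not leave room "
                f"for a {min_run}-week qualifying run in {n_weeks} weeks"
            )
        run = min(week + min_run + 1, n_weeks) - week
        if episode.episode_type == "manic":
            asrm[week : week + run] = rng.integers(8, 16, size=run)
        else:
            ids[week : week + run] = rng.integers(30, 46, size=run)

    dates = pd.date_range(start_date.normalize(), periods=n_weeks, freq="7D")
    return QuestionnaireSeries(
        patient_id=patient_id, week_start_dates=dates, asrm=asrm, ids_sr=ids
    )


def simulate_patient(
    params: CircadianParams,
    transition: TransitionSpec | None = None,
    n_weeks: int | None = None,
    patient_id: str = "sim",
):
    """Generate a full synthetic patient: activity, symptoms and ground truth.

    Returns ``(activity, symptoms, truth)`` where ``truth`` records the seed
    and the injected onset/switch days for later scoring.  Sub-seeds for the
    activity and symptom generators are derived deterministically from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    act_seed, sym_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    act_params = CircadianParams(
        n_days=params.n_days,
        mesor=params.mesor,
        amplitude=params.amplitude,
        noise_sd=params.noise_sd,
        acrophase_minute=params.acrophase_minute,
        clip_at_zero=params.clip_at_zero,
        seed=act_seed,
    )
    activity = generate_circadian_series(act_params, patient_id=patient_id)
    if transition is not None:
        activity = inject_transition_signature(activity, transition, act_params)
    if n_weeks is None:
        n_weeks = params.n_days // 7
        if transition is not None:
            min_run = 2 if transition.episode_type == "manic" else 3
            n_weeks = max(n_weeks, transition.onset_week + min_run)
    symptoms = generate_symptom_series(
        n_weeks, episode=transition, seed=sym_seed, patient_id=patient_id
    )
    truth = {
        "patient_id": patient_id,
        "seed": params.seed,
        "onset_day": None if transition is None else transition.onset_day,
        "onset_week": None if transition is None else transition.onset_week,
        "episode_type": None if transition is None else transition.episode_type,
        "switch_day": None if transition is None else transition.switch_day,
        "rhythm_switch_period": None if transition is None else transition.rhythm_switch_period,
    }
    return activity, symptoms, truth
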