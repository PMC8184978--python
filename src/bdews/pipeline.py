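"""Per-patient analysis orchestration and group-level combination.

``analyze_patient`` runs the full chain on one patient: detect the first
episode onset from weekly symptoms, detrend the minute series, cut rolling
7-day windows, compute the three early-warning indicators, Mann-Kendall-test
each indicator over the four pre-onset weeks, compute the rolling harmonic
ratio with WARN/SWITCH rhythm events on the raw counts, and compare weekly
mean activity against the euthymic reference.  ``combine_group`` pools the
per-patient p-values per indicator with Fisher's method and tallies the
significance counts clinicians care about (patients with any significant
indicator, with all three, with a significant acf-720 decrease/increase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .episodes import AnalysisIntervals, EpisodeOnset, analysis_intervals, detect_episode_onset
from .indicators import (
    INDICATORS,
    EWSSeries,
    MeanActivityComparison,
    compare_mean_activity,
    interval_mean,
    rolling_ews,
)
from .io_formats import ActivitySeries, QuestionnaireSeries
from .preprocess import WindowSpec, detrend_linear, make_windows
from .spectral import HarmonicSummary, RhythmEvent, detect_rhythm_transition, rolling_harmonic_ratio
from .trend import FisherResult, MannKendallResult, fisher_combine, mann_kendall, significance_label

__all__ = [
    "AnalysisConfig",
    "IndicatorRow",
    "PatientReport",
    "GroupReport",
    "analyze_patient",
    "combine_group",
    "significance_counts",
    "patient_report_frame",
    "ews_series_frame",
    "ratio_series_frame",
    "group_report_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Declarative knobs of the whole pipeline (one YAML file for the CLI)."""

    window: WindowSpec = field(default_factory=WindowSpec)
    acf_lag: int = 720
    alpha: float = 0.05
    warn_threshold: float = 0.9
    switch_threshold: float = 1.0
    pre_onset_days: int = 28
    euthymic: tuple[int, int] | None = None  # explicit override, days
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        window = WindowSpec(
            window_length=int(raw.get("window_days", 7)) * 1440,
            step=int(raw.get("step_days", 1)) * 1440,
            min_completeness=float(raw.get("min_completeness", 0.9)),
        )
        euth = raw.get("euthymic")
        return cls(
            window=window,
            acf_lag=int(raw.get("acf_lag", 720)),
            alpha=float(raw.get("alpha", 0.05)),
            warn_threshold=float(raw.get("warn_threshold", 0.9)),
            switch_threshold=float(raw.get("switch_threshold", 1.0)),
            pre_onset_days=int(raw.get("pre_onset_days", 28)),
            euthymic=tuple(euth) if euth else None,
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class IndicatorRow:
    """One line of the per-patient report: trend test of one indicator."""

    indicator: str
    result: MannKendallResult | None
    status: str  # "ok" | "untestable" | "no transition"

    @property
    def sig(self) -> str:
        return significance_label(self.result.p) if self.result else ""


@dataclass
class PatientReport:
    patient_id: str
    onset: EpisodeOnset | None
    intervals: AnalysisIntervals | None
    rows: list[IndicatorRow]
    ews: dict[str, EWSSeries] | None
    ratio_series: list[HarmonicSummary]
    events: list[RhythmEvent]
    mean_activity_pre: MeanActivityComparison | None
    mean_activity_during: MeanActivityComparison | None

    @property
    def episode_type(self) -> str | None:
        return self.onset.episode_type if self.onset else None


@dataclass
class GroupReport:
    fisher: dict[str, FisherResult]
    counts: dict[str, int]
    n_patients: int


def analyze_patient(
    activity: ActivitySeries,
    symptoms: QuestionnaireSeries,
    config: AnalysisConfig | None = None,
) -> PatientReport:
    """Full single-patient analysis; see the module docstring for the chain.

    A patient without a detectable transition gets a report whose indicator
    rows are marked "no transition" (such patients are excluded from trend
    testing, mirroring the study design); a pre-onset span with fewer than
    3 usable indicator values marks the row "untestable".
    """
    config = config or AnalysisConfig()
    n_days = int(activity.n_epochs // 1440)

    onset = detect_episode_onset(symptoms)
    if onset is None:
        logger.info("%s: no qualifying symptom transition", activity.patient_id)
        rows = [IndicatorRow(name, None, "no transition") for name in INDICATORS]
        return PatientReport(
            patient_id=activity.patient_id,
            onset=None,
            intervals=None,
            rows=rows,
            ews=None,
            ratio_series=[],
            events=[],
            mean_activity_pre=None,
            mean_activity_during=None,
        )

    intervals = analysis_intervals(
        onset,
        n_days,
        euthymic=config.euthymic,
        questionnaire=symptoms,
        pre_onset_days=config.pre_onset_days,
    )
    logger.info(
        "%s: %s onset day %d, pre-onset %s (n=%d), euthymic %s",
        activity.patient_id, onset.episode_type, onset.onset_day,
        intervals.pre_onset, intervals.pre_onset_n, intervals.euthymic,
    )

    detrended = detrend_linear(activity)
    windowed = make_windows(detrended, config.window)
    ews = rolling_ews(windowed, lag=config.acf_lag)

    rows = []
    for name in INDICATORS:
        pre = ews[name].restrict_days(*intervals.pre_onset)
        n_usable = int(pre.mask.sum())
        if n_usable < 3:
            rows.append(IndicatorRow(name, None, "untestable"))
            continue
        rows.append(IndicatorRow(name, mann_kendall(pre.values), "ok"))

    # spectra on raw counts (detrending would not change them after per-window
    # mean removal, but the published convention computes them on raw data)
    raw_windowed = make_windows(activity, config.window)
    ratio_series = rolling_harmonic_ratio(raw_windowed)
    events = detect_rhythm_transition(
        ratio_series,
        warn_threshold=config.warn_threshold,
        switch_threshold=config.switch_threshold,
    )

    mean_pre = mean_during = None
    if intervals.euthymic is not None:
        ref = interval_mean(activity, intervals.euthymic[0], intervals.euthymic[0] + 7)
        pre_week = interval_mean(activity, onset.onset_day - 7, onset.onset_day)
        mean_pre = compare_mean_activity(ref, pre_week)
        if onset.onset_day < n_days:
            during_week = interval_mean(activity, onset.onset_day, onset.onset_day + 7)
            mean_during = compare_mean_activity(ref, during_week)

    return PatientReport(
        patient_id=activity.patient_id,
        onset=onset,
        intervals=intervals,
        rows=rows,
        ews=ews,
        ratio_series=ratio_series,
        events=events,
        mean_activity_pre=mean_pre,
        mean_activity_during=mean_during,
    )


def significance_counts(rows: pd.DataFrame, alpha: float = 0.05) -> dict[str, int]:
    """Patient-level significance tallies from a tidy (patient, indicator, p, tau) table.

    Direction is taken from the sign of tau (equivalently S); significance is
    p ≤ alpha, two-sided.
    """
    sig = rows["p"] <= alpha
    per_patient = sig.groupby(rows["patient"])
    acf = rows[rows["indicator"] == "acf720"]
    acf_sig = acf["p"] <= alpha
    return {
        "n_patients": int(rows["patient"].nunique()),
        "any_significant": int(per_patient.any().sum()),
        "all_three_significant": int((per_patient.sum() == 3).sum()),
        "acf720_significant_decrease": int((acf_sig & (acf["tau"] < 0)).sum()),
        "acf720_significant_increase": int((acf_sig & (acf["tau"] > 0)).sum()),
    }


def combine_group(reports: Sequence[PatientReport], alpha: float = 0.05) -> GroupReport:
    """Fisher-combine per-indicator p-values across patients and tally counts."""
    records = []
    for rep in reports:
        for row in rep.rows:
            if row.status == "ok" and row.result is not None:
                records.append(
                    {
                        "patient": rep.patient_id,
                        "indicator": row.indicator,
                        "p": row.result.p,
                        "tau": row.result.tau,
                    }
                )
    if not records:
        raise ValueError("no testable indicator rows across reports")
    df = pd.DataFrame(records)
    fisher = {
        name: fisher_combine(df.loc[df["indicator"] == name, "p"].to_numpy())
        for name in INDICATORS
        if (df["indicator"] == name).any()
    }
    return GroupReport(
        fisher=fisher,
        counts=significance_counts(df, alpha=alpha),
        n_patients=int(df["patient"].nunique()),
    )


# ---------------------------------------------------------------------------
# tabular exports


def patient_report_frame(report: PatientReport) -> pd.DataFrame:
    """Per-indicator trend-test table: id, episode_type, indicator, z, tau, n, p, sig, direction."""
    rows = []
    for r in report.rows:
        res = r.result
        rows.append(
            {
                "id": report.patient_id,
                "episode_type": report.episode_type or "",
                "indicator": r.indicator,
                "z": res.z if res else np.nan,
                "tau": res.tau if res else np.nan,
                "n": res.n if res else 0,
                "p": res.p if res else np.nan,
                "sig": r.sig,
                "direction": res.direction if res else r.status,
            }
        )
    return pd.DataFrame(rows)


def ews_series_frame(report: PatientReport) -> pd.DataFrame:
    """Indicator series table: end_day, variance, kurtosis, acf720, usable."""
    if report.ews is None:
        return pd.DataFrame(columns=["end_day", *INDICATORS, "usable"])
    end_days = report.ews["variance"].end_days
    df = pd.DataFrame({"end_day": end_days})
    for name in INDICATORS:
        df[name] = report.ews[name].values
    df["usable"] = report.ews["variance"].mask
    return df


def ratio_series_frame(report: PatientReport) -> pd.DataFrame:
    """Harmonic-ratio table: end_day, ratio, dominant_period_min, event."""
    event_by_day = {}
    for e in report.events:
        event_by_day.setdefault(e.end_day, []).append(e.kind)
    rows = [
        {
            "end_day": s.window_end_day,
            "ratio": s.ratio,
            "dominant_period_min": s.dominant_period,
            "event": "+".join(event_by_day.get(s.window_end_day, [])),
        }
        for s in report.ratio_series
    ]
    return pd.DataFrame(rows, columns=["end_day", "ratio", "dominant_period_min", "event"])


def group_report_frame(group: GroupReport) -> pd.DataFrame:
    rows = [
        {
            "indicator": name,
            "chi2": fr.chi2,
            "df": fr.df,
            "combined_p": fr.p,
        }
        for name, fr in group.fisher.items()
    ]
    df = pd.DataFrame(rows)
    for key, value in group.counts.items():
        df[key] = value
    return df
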