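"""Episode onset from weekly symptom scores, and the analysis intervals.

A manic episode begins at the first week that opens a run of at least two
consecutive weeks with ASRM > 5; a depressive episode at the first week
opening a run of at least three consecutive weeks with IDS-SR > 25.  Both
thresholds are strict (a score of exactly 5 / 25 does not qualify) and a
missing week breaks a run.  Only the first transition of a patient is
analysed; onset is dated to the first day of the first qualifying week,
the finest resolution weekly assessments allow.

The pre-onset interval for trend testing is the four weeks ending at onset
(shorter when onset falls early in the recording).  The euthymic reference
interval is either supplied explicitly or derived as the longest run of
weeks below both symptom thresholds that ends before the pre-onset
interval begins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import QuestionnaireSeries

__all__ = [
    "EpisodeOnset",
    "AnalysisIntervals",
    "detect_episode_onset",
    "analysis_intervals",
    "MANIC_THRESHOLD",
    "DEPRESSIVE_THRESHOLD",
]

MANIC_THRESHOLD = 5      # ASRM, strict
MANIC_MIN_WEEKS = 2
DEPRESSIVE_THRESHOLD = 25  # IDS-SR, strict
DEPRESSIVE_MIN_WEEKS = 3

PRE_ONSET_DAYS = 28
WINDOW_DAYS = 7


@dataclass
class EpisodeOnset:
    episode_type: str  # "manic" | "depressive"
    onset_week_index: int
    onset_day: int  # day offset of the qualifying week's start from the series start
    qualifying_run_length: int


@dataclass
class AnalysisIntervals:
    """Half-open day intervals for pre-onset trend testing and the euthymic reference."""

    pre_onset: tuple[int, int]
    euthymic: tuple[int, int] | None
    pre_onset_n: int


def _first_qualifying_run(scores: np.ndarray, threshold: float, min_weeks: int):
    """(start, length) of the first maximal run of > threshold weeks with length >= min_weeks."""
    above = np.asarray(scores, dtype=float) > threshold  # NaN compares False: missing breaks runs
    i, n = 0, above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_weeks:
                return i, j - i
            i = j
        else:
            i += 1
    return None


def detect_episode_onset(q: QuestionnaireSeries) -> EpisodeOnset | None:
    """First manic or depressive onset in the weekly scores, or None.

    When qualifying manic and depressive runs begin in the same week the
    case is ambiguous at weekly resolution and a ValueError asks for manual
    adjudication.
    """
    if q.n_weeks < 2:
        raise ValueError("need at least 2 weeks of symptom data")
    manic = _first_qualifying_run(q.asrm, MANIC_THRESHOLD, MANIC_MIN_WEEKS)
    depressive = _first_qualifying_run(q.ids_sr, DEPRESSIVE_THRESHOLD, DEPRESSIVE_MIN_WEEKS)
    if manic is None and depressive is None:
        return None
    if manic is not None and depressive is not None:
        if manic[0] == depressive[0]:
            raise ValueError(
                f"manic and depressive criteria first qualify in the same week "
                f"({manic[0]}): manual adjudication required"
            )
        chosen, kind = (manic, "manic") if manic[0] < depressive[0] else (depressive, "depressive")
    elif manic is not None:
        chosen, kind = manic, "manic"
    else:
        chosen, kind = depressive, "depressive"
    start, length = chosen
    return EpisodeOnset(
        episode_type=kind,
        onset_week_index=start,
        onset_day=start * 7,
        qualifying_run_length=length,
    )


def analysis_intervals(
    onset: EpisodeOnset,
    n_days: int,
    euthymic: tuple[int, int] | None = None,
    questionnaire: QuestionnaireSeries | None = None,
    pre_onset_days: int = PRE_ONSET_DAYS,
) -> AnalysisIntervals:
    """Pre-onset and euthymic day intervals for one detected onset.

    ``pre_onset`` is the (at most) four weeks ending at onset.  The euthymic
    interval may be given explicitly; otherwise, when ``questionnaire`` is
    supplied, it is the longest run of sub-threshold weeks (ASRM ≤ 5 and
    IDS-SR ≤ 25, both observed) lying entirely before the pre-onset
    interval; with neither it is None.  ``pre_onset_n`` counts the daily
    window-end labels inside ``pre_onset`` — at most 28, fewer when onset
    falls within the first five weeks of recording.
    """
    if not 0 <= onset.onset_day <= n_days:
        raise ValueError("onset lies outside the series span")
    if onset.onset_day == 0:
        raise ValueError("onset on day 0: no pre-onset data to analyse")
    pre = (max(0, onset.onset_day - pre_onset_days), onset.onset_day)

    if euthymic is None and questionnaire is not None:
        euthymic = _auto_euthymic(questionnaire, before_day=pre[0])

    # full 7-day windows end on days 7..n_days; count end days inside pre
    first_end = max(pre[0], WINDOW_DAYS)
    pre_n = max(0, pre[1] - first_end)
    return AnalysisIntervals(pre_onset=pre, euthymic=euthymic, pre_onset_n=pre_n)


def _auto_euthymic(q: QuestionnaireSeries, before_day: int) -> tuple[int, int] | None:
    n_eligible_weeks = before_day // 7  # weeks ending on or before before_day
    if n_eligible_weeks < 1:
        return None
    asrm = q.asrm[:n_eligible_weeks]
    ids = q.ids_sr[:n_eligible_weeks]
    ok = (
        np.isfinite(asrm)
        & np.isfinite(ids)
        & (asrm <= MANIC_THRESHOLD)
        & (ids <= DEPRESSIVE_THRESHOLD)
    )
    best = None  # (length, start)
    i, n = 0, ok.size
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if best is None or j - i > best[0]:
                best = (j - i, i)
            i = j
        else:
            i += 1
    if best is None:
        return None
    length, start = best
    return (start * 7, (start + length) * 7)
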