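"""Reading, writing and validation of actigraphy and weekly-symptom tables.

The canonical on-disk formats are plain delimited text:

* activity table — columns ``timestamp,counts`` (header required), one row
  per observed 1-minute epoch, ISO-8601 timestamps.  Gaps in the timestamp
  sequence become missing (off-wrist) epochs; an empty ``counts`` cell also
  marks a missing epoch.
* symptom table — columns ``week_start_date,asrm,ids_sr``, one row per
  weekly self-report (ASRM 0-20, IDS-SR 0-84).

Missing epochs are represented explicitly through a validity mask rather
than zero counts, because zero is a legitimate activity value (sleep).
Timestamps are interpreted as local wall-clock time; duplicate or
backwards-jumping wall-clock epochs are rejected rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "QuestionnaireSeries",
    "read_activity_table",
    "write_activity_table",
    "read_symptom_table",
    "write_symptom_table",
    "EPOCH_MINUTES",
    "ASRM_RANGE",
    "IDS_SR_RANGE",
]

#: Epoch length of the actigraph export, minutes.
EPOCH_MINUTES = 1

#: Valid score ranges of the two weekly instruments (inclusive).
ASRM_RANGE = (0, 20)
IDS_SR_RANGE = (0, 84)

MINUTES_PER_DAY = 1440


@dataclass
class ActivitySeries:
    """Uniformly spaced 1-minute-epoch activity counts with a missingness mask.

    ``counts`` is a float array holding NaN at missing epochs; ``valid_mask``
    is the authoritative missingness indicator.  Raw device counts are
    non-negative, but detrended residual series (which reuse this container)
    may hold negative values, so non-negativity is enforced at read time,
    not here.
    """

    patient_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    valid_mask: np.ndarray | None = None
    epoch_length: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(minutes=EPOCH_MINUTES))

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a 1-d sequence of length >= 1")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.counts)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.counts.shape:
            raise ValueError("valid_mask must have the same length as counts")
        # missing epochs carry no count value
        self.counts = np.where(self.valid_mask, self.counts, np.nan)
        observed = self.counts[self.valid_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed counts must be finite")

    @property
    def n_epochs(self) -> int:
        return self.counts.size

    @property
    def n_days(self) -> float:
        return self.n_epochs / MINUTES_PER_DAY

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_epochs, freq=self.epoch_length)

    def with_counts(self, counts: np.ndarray, valid_mask: np.ndarray | None = None) -> "ActivitySeries":
        """Copy of this series with new values (same grid and identity)."""
        return replace(
            self,
            counts=np.asarray(counts, dtype=float),
            valid_mask=self.valid_mask.copy() if valid_mask is None else valid_mask,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps(), "counts": self.counts})


@dataclass
class QuestionnaireSeries:
    """Weekly ASRM and IDS-SR self-report scores for one patient.

    Scores are stored as floats with NaN marking a skipped week so that
    integer scores and missingness coexist; week starts must be exactly
    seven days apart.
    """

    patient_id: str
    week_start_dates: pd.DatetimeIndex
    asrm: np.ndarray
    ids_sr: np.ndarray

    def __post_init__(self) -> None:
        self.week_start_dates = pd.DatetimeIndex(self.week_start_dates)
        self.asrm = np.asarray(self.asrm, dtype=float)
        self.ids_sr = np.asarray(self.ids_sr, dtype=float)
        n = len(self.week_start_dates)
        if self.asrm.shape != (n,) or self.ids_sr.shape != (n,):
            raise ValueError("asrm and ids_sr must match week_start_dates in length")
        if n > 1:
            diffs = np.diff(self.week_start_dates.asi8)
            week_ns = pd.Timedelta(days=7).value
            if np.any(diffs <= 0):
                raise ValueError("week_start_dates must be strictly increasing")
            if np.any(diffs != week_ns):
                bad = int(np.argmax(diffs != week_ns)) + 1
                raise ValueError(
                    f"consecutive weeks must be exactly 7 days apart (row {bad})"
                )
        _check_score_range(self.asrm, ASRM_RANGE, "asrm")
        _check_score_range(self.ids_sr, IDS_SR_RANGE, "ids_sr")

    @property
    def n_weeks(self) -> int:
        return len(self.week_start_dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start_date": self.week_start_dates.strftime("%Y-%m-%d"),
                "asrm": self.asrm,
                "ids_sr": self.ids_sr,
            }
        )


def _check_score_range(scores: np.ndarray, bounds: tuple[int, int], name: str) -> None:
    observed = scores[np.isfinite(scores)]
    lo, hi = bounds
    if observed.size and (observed.min() < lo or observed.max() > hi):
        raise ValueError(f"{name} scores must lie in [{lo}, {hi}] or be missing")


def read_activity_table(
    path: str | Path,
    dialect: dict | None = None,
) -> ActivitySeries:
    """Read a ``timestamp,counts`` table into a validated :class:`ActivitySeries`.

    Gaps in the timestamp sequence are filled with missing epochs so that the
    returned series is contiguous at 1-minute spacing.  ``dialect`` may
    override ``sep``, ``timestamp_col``, ``count_col`` and ``patient_id`` for
    non-canonical exports (e.g. a MotionWatch-8 CSV with renamed columns).

    Raises
    ------
    ValueError
        on non-monotonic or duplicate timestamps, negative counts, or
        timestamps off the 1-minute grid; the message names the first
        offending row (0-based, excluding the header).
    """
    path = Path(path)
    opts = {"sep": ",", "timestamp_col": "timestamp", "count_col": "counts", "patient_id": None}
    if dialect:
        opts.update(dialect)
    df = pd.read_csv(path, sep=opts["sep"], float_precision="round_trip")
    for col in (opts["timestamp_col"], opts["count_col"]):
        if col not in df.columns:
            raise ValueError(f"activity table {path} lacks required column {col!r}")
    ts = pd.to_datetime(df[opts["timestamp_col"]])
    if ts.isna().any():
        raise ValueError(f"unparseable timestamp at row {int(ts.isna().idxmax())}")
    diffs = ts.diff()
    if (diffs == pd.Timedelta(0)).any():
        row = int((diffs == pd.Timedelta(0)).idxmax())
        raise ValueError(f"duplicate timestamp at row {row}")
    if (diffs < pd.Timedelta(0)).any():
        row = int((diffs < pd.Timedelta(0)).idxmax())
        raise ValueError(f"non-monotonic timestamp at row {row}")
    offsets = (ts - ts.iloc[0]) / pd.Timedelta(minutes=EPOCH_MINUTES)
    if not np.all(offsets == np.round(offsets)):
        row = int(np.argmax(offsets != np.round(offsets)))
        raise ValueError(f"timestamp off the {EPOCH_MINUTES}-minute grid at row {row}")
    counts = pd.to_numeric(df[opts["count_col"]], errors="raise").astype(float)
    if (counts.dropna() < 0).any():
        row = int((counts < 0).idxmax())
        raise ValueError(f"negative count at row {row}")

    n_epochs = int(offsets.iloc[-1]) + 1
    full = np.full(n_epochs, np.nan)
    full[offsets.astype(int).to_numpy()] = counts.to_numpy()
    patient_id = opts["patient_id"] or path.stem
    return ActivitySeries(patient_id=patient_id, start_time=ts.iloc[0], counts=full)


def write_activity_table(series: ActivitySeries, path: str | Path) -> None:
    """Write the series as a ``timestamp,counts`` table (missing → empty cell)."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    # shortest round-trippable decimal repr so write∘read is the identity
    df["counts"] = [repr(float(c)) if np.isfinite(c) else "" for c in series.counts]
    df.to_csv(path, index=False)


def read_symptom_table(path: str | Path, patient_id: str | None = None) -> QuestionnaireSeries:
    """Read a ``week_start_date,asrm,ids_sr`` table into a :class:`QuestionnaireSeries`."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("week_start_date", "asrm", "ids_sr"):
        if col not in df.columns:
            raise ValueError(f"symptom table {path} lacks required column {col!r}")
    dates = pd.DatetimeIndex(pd.to_datetime(df["week_start_date"]))
    return QuestionnaireSeries(
        patient_id=patient_id or path.stem,
        week_start_dates=dates,
        asrm=pd.to_numeric(df["asrm"]).to_numpy(dtype=float),
        ids_sr=pd.to_numeric(df["ids_sr"]).to_numpy(dtype=float),
    )


def write_symptom_table(q: QuestionnaireSeries, path: str | Path) -> None:
    q.to_frame().to_csv(path, index=False)
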