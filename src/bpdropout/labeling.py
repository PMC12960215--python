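"""Inactivity / resumption event definitions and 14-day window labeling.

Event logic operates on integer day indices (days since the fixed Monday
calendar origin) at day granularity: multiple readings on one calendar day
collapse to a single *measured day* for event purposes, while reading counts
are preserved for feature extraction.

Definitions:

* **inactive at day t**: no measurement in the closed interval
  ``[t - 27, t]`` (the 28-day rule);
* **resumption after day a**: the earliest measured day ``r > a`` such that
  each of the four weekly windows ``[r, r+6] .. [r+21, r+27]`` contains at
  least one measurement, confirmable before the dataset cutoff;
* **observation window**: a 14-day segment; each user's stream is cut into
  consecutive non-overlapping windows anchored at their first measured day;
* **horizon label** ``y_X``: inactive status evaluated at ``end + X`` for X
  on the 28..91 step-7 grid, undefined when follow-up is insufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    CALENDAR_ORIGIN,
    HORIZON_GRID,
    INACTIVITY_THRESHOLD_DAYS,
    NON_RESUMPTION_FOLLOWUP_DAYS,
    WINDOW_DAYS,
    ConfigError,
)


class InsufficientFollowup(ValueError):
    """The requested evaluation day lies beyond the dataset cutoff."""


@dataclass
class DailySeries:
    """Day-indexed measurement stream of one user.

    ``days`` are the sorted unique measured day indices, ``counts`` the
    number of readings on each, and ``readings`` one row per reading
    (columns: day, sbp, dbp, pulse).  ``cutoff_day`` is the last observed
    calendar day of the whole dataset, not of this user.
    """

    user_id: str
    days: np.ndarray
    counts: np.ndarray
    cutoff_day: int
    readings: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.days.size:
            if np.any(np.diff(self.days) <= 0):
                raise ValueError("days must be strictly increasing")
            if np.any(self.counts < 1):
                raise ValueError("counts must be >= 1 on measured days")
            if self.days[-1] > self.cutoff_day:
                raise ValueError("measured day beyond cutoff")

    def reading_arrays(self):
        """Cached numpy views of the readings: (day-per-reading, {vital:
        values}, index of each measured day's first reading)."""
        cache = getattr(self, "_reading_cache", None)
        if cache is None:
            day = self.readings["day"].to_numpy(dtype=np.int64)
            vitals = {
                v: self.readings[v].to_numpy(dtype=float)
                for v in ("sbp", "dbp", "pulse")
            }
            starts = np.searchsorted(day, self.days)
            cache = (day, vitals, starts)
            object.__setattr__(self, "_reading_cache", cache)
        return cache

    @property
    def first_day(self) -> int:
        if not self.days.size:
            raise ValueError("empty series has no first_day")
        return int(self.days[0])

    @property
    def last_day(self) -> int:
        return int(self.days[-1])

    def has_measurement(self, lo: int, hi: int) -> bool:
        """Any measured day in the closed interval [lo, hi]?"""
        i = np.searchsorted(self.days, lo, side="left")
        return bool(i < self.days.size and self.days[i] <= hi)


@dataclass(frozen=True)
class ObservationWindow:
    user_id: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day - self.start_day + 1 != WINDOW_DAYS:
            raise ValueError("window must span exactly 14 days")


@dataclass(frozen=True)
class GapEpisode:
    """A maximal run of unmeasured days following a measured day."""

    user_id: str
    gap_start: int
    gap_length: int
    followup_days: int
    resumed_within_180: bool | None


def day_index(dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Calendar dates -> integer day indices relative to the Monday origin."""
    ts = pd.to_datetime(dates)
    origin = pd.Timestamp(CALENDAR_ORIGIN)
    return ((ts - origin) // pd.Timedelta(days=1)).to_numpy(dtype=np.int64)


def build_daily_series(
    measurements: pd.DataFrame, cutoff_day: int | None = None
) -> dict[str, DailySeries]:
    """Group per-reading records into one :class:`DailySeries` per user.

    ``cutoff_day`` defaults to the last measured day across the dataset.
    """
    if measurements.empty:
        return {}
    df = measurements.copy()
    df["day"] = day_index(df["date"])
    if cutoff_day is None:
        cutoff_day = int(df["day"].max())
    out: dict[str, DailySeries] = {}
    df = df.sort_values(["user_id", "day"], kind="stable")
    for uid, grp in df.groupby("user_id", sort=True):
        days, counts = np.unique(grp["day"].to_numpy(), return_counts=True)
        out[str(uid)] = DailySeries(
            user_id=str(uid),
            days=days,
            counts=counts,
            cutoff_day=cutoff_day,
            readings=grp[["day", "sbp", "dbp", "pulse"]].reset_index(drop=True),
        )
    return out


# ---------------------------------------------------------------------------
# event logic


def inactive_at(
    series: DailySeries, t: int, threshold: int = INACTIVITY_THRESHOLD_DAYS
) -> bool:
    """True iff no measurement occurred in the closed interval [t-threshold+1, t].

    Days before the user's first measurement count as unmeasured only once the
    user exists (t >= first_day); for t < first_day the user has not started
    and the state is False by convention.
    """
    if t > series.cutoff_day:
        raise InsufficientFollowup(f"day {t} beyond cutoff {series.cutoff_day}")
    if not series.days.size or t < series.first_day:
        return False
    return not series.has_measurement(t - threshold + 1, t)


def segment_windows(series: DailySeries) -> list[ObservationWindow]:
    """Cut [first_day, cutoff] into consecutive 14-day windows; the trailing
    partial segment is discarded.  Oldest first."""
    if not series.days.size:
        return []
    first = series.first_day
    span = series.cutoff_day - first + 1
    k = span // WINDOW_DAYS
    return [
        ObservationWindow(
            series.user_id, first + i * WINDOW_DAYS, first + (i + 1) * WINDOW_DAYS - 1
        )
        for i in range(k)
    ]


def label_window(
    series: DailySeries,
    window: ObservationWindow,
    X: int,
    threshold: int = INACTIVITY_THRESHOLD_DAYS,
) -> int | None:
    """Inactive status X days after the window end; None when follow-up is
    insufficient (end + X beyond cutoff)."""
    if X not in HORIZON_GRID:
        raise ConfigError(f"horizon {X} off the 28..91 step-7 grid")
    t = window.end_day + X
    if t > series.cutoff_day:
        return None
    return int(inactive_at(series, t, threshold))


def detect_gaps(series: DailySeries) -> list[GapEpisode]:
    """Maximal runs of unmeasured days, each following a measured day.

    The trailing run after the last measurement extends to the cutoff and is
    included.  ``resumed_within_180`` is defined only for episodes with at
    least 180 days of follow-up after gap_start; within that horizon an
    episode counts as resumed iff a confirmed resumption day starts within
    180 days of gap_start.
    """
    if not series.days.size:
        return []
    episodes: list[GapEpisode] = []
    days = series.days
    boundaries = list(zip(days[:-1], days[1:]))
    runs = [(int(a) + 1, int(b) - int(a) - 1) for a, b in boundaries if b - a > 1]
    if series.cutoff_day > series.last_day:
        runs.append((series.last_day + 1, series.cutoff_day - series.last_day))
    for gap_start, gap_length in runs:
        followup = series.cutoff_day - gap_start + 1
        resumed: bool | None
        if followup < NON_RESUMPTION_FOLLOWUP_DAYS:
            resumed = None
        else:
            r = detect_resumption(series, gap_start - 1)
            resumed = r is not None and (r - gap_start) < NON_RESUMPTION_FOLLOWUP_DAYS
        episodes.append(
            GapEpisode(series.user_id, gap_start, gap_length, followup, resumed)
        )
    return episodes


def detect_resumption(series: DailySeries, after_day: int) -> int | None:
    """Earliest measured day r > after_day such that each of the four weekly
    windows [r, r+6] .. [r+21, r+27] contains a measurement and the pattern is
    confirmable before the cutoff (r + 27 <= cutoff).  None otherwise."""
    if after_day > series.cutoff_day:
        raise InsufficientFollowup("after_day beyond cutoff")
    days = series.days
    i = np.searchsorted(days, after_day, side="right")
    for r in days[i:]:
        r = int(r)
        if r + 27 > series.cutoff_day:
            return None
        if all(series.has_measurement(r + 7 * w, r + 7 * w + 6) for w in range(4)):
            return r
    return None


# ---------------------------------------------------------------------------
# cohort-level labeling table


def label_cohort(
    series_map: dict[str, DailySeries],
    horizons: tuple[int, ...] = HORIZON_GRID,
    keep_empty_windows: bool = True,
) -> pd.DataFrame:
    """One row per (user, window) with start/end days and per-horizon labels.

    Columns: user_id, start_day, end_day, then ``y_X`` (0/1, -1 where
    undefined) and ``defined_X`` flags for each horizon X.
    """
    rows = []
    for uid in sorted(series_map):
        series = series_map[uid]
        for w in segment_windows(series):
            if not keep_empty_windows and not series.has_measurement(
                w.start_day, w.end_day
            ):
                continue
            rec: dict = {
                "user_id": uid,
                "start_day": w.start_day,
                "end_day": w.end_day,
            }
            for X in horizons:
                y = label_window(series, w, X)
                rec[f"y_{X}"] = -1 if y is None else y
                rec[f"defined_{X}"] = y is not None
            rows.append(rec)
    cols = ["user_id", "start_day", "end_day"]
    cols += [f"y_{X}" for X in horizons] + [f"defined_{X}" for X in horizons]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def write_windows(table: pd.DataFrame, path: str | Path) -> None:
    table.to_parquet(path, index=False)


def read_windows(path: str | Path) -> pd.DataFrame:
    return pd.read_parquet(path)


def first_inactive_onset(
    series: DailySeries, threshold: int = INACTIVITY_THRESHOLD_DAYS
) -> int | None:
    """First day t with inactive_at(series, t) true, i.e. 27 days after the
    start of the first gap of length >= threshold; None if never observed."""
    if not series.days.size:
        return None
    days = series.days
    gaps_after = np.diff(days) - 1
    hit = np.nonzero(gaps_after >= threshold)[0]
    candidates = []
    if hit.size:
        candidates.append(int(days[hit[0]]) + threshold)
    trailing_start = series.last_day + 1
    if series.cutoff_day - trailing_start + 1 >= threshold:
        candidates.append(trailing_start + threshold - 1)
    return min(candidates) if candidates else None
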