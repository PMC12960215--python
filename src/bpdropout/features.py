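"""Per-window measurement-pattern, vital-sign and demographic features.

Each 14-day observation window yields one named feature vector.  The
catalogue covers three groups:

* ``pattern`` - counts and timing of measurement days: totals, week-1/week-2
  decomposition and their deltas (overall and restricted to weekdays /
  weekends of the fixed Monday-anchored calendar), streaks, in-window gaps,
  and history features (days since last/first measurement, activity in the
  user's first two weeks);
* ``vitals`` - per-window summary statistics of SBP, DBP and pulse readings,
  including a per-day least-squares slope;
* ``demographic`` - age at window end (completed years from birth
  year-month) plus the two sex flags: ``is_female`` and ``sex_provided``.

Missing values (e.g. vital statistics of a window with no readings) are coded
as NaN and propagated to models that accept them; they are never silently
imputed here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import CALENDAR_ORIGIN, WINDOW_DAYS

from .labeling import DailySeries, ObservationWindow

_ORIGIN = pd.Timestamp(CALENDAR_ORIGIN)

_VITALS = ("sbp", "dbp", "pulse")
_VITAL_STATS = ("mean", "sd", "min", "max", "last_minus_first", "slope_per_day")

_PATTERN = [
    ("n_meas_total", "count.readings_in_window"),
    ("n_days_measured", "count.days_with_reading"),
    ("days_since_last_meas", "timing.end_minus_last_measured_day"),
    ("days_since_first_meas", "timing.end_minus_user_first_day"),
    ("n_meas_first14", "history.readings_in_user_first_14_days"),
    ("daily_count_mean", "daily.mean_readings_over_14_days"),
    ("daily_count_sd", "daily.sd_readings_over_14_days"),
    ("daily_count_max", "daily.max_readings_over_14_days"),
    ("n_days_week1", "week.days_measured_days_1_7"),
    ("n_days_week2", "week.days_measured_days_8_14"),
    ("delta_days_all", "week.week2_minus_week1_days"),
    ("delta_days_weekday", "week.week2_minus_week1_weekdays"),
    ("delta_days_weekend", "week.week2_minus_week1_weekend_days"),
    ("max_gap_in_window", "gap.longest_unmeasured_run"),
    ("longest_streak", "gap.longest_measured_run"),
    ("meas_per_measured_day", "daily.readings_per_measured_day"),
]

_DEMOGRAPHIC = [
    ("age_years", "demo.completed_years_at_window_end"),
    ("is_female", "demo.flag_female"),
    ("sex_provided", "demo.flag_sex_reported"),
]


def feature_catalogue() -> list[tuple[str, str, str]]:
    """Stable ordered list of (name, formula-id, group)."""
    cat = [(n, f, "pattern") for n, f in _PATTERN]
    for v in _VITALS:
        for s in _VITAL_STATS:
            cat.append((f"{v}_{s}", f"vital.{s}[{v}]", "vitals"))
    cat += [(n, f, "demographic") for n, f in _DEMOGRAPHIC]
    return cat


FEATURE_NAMES = [name for name, _, _ in feature_catalogue()]


def catalogue_to_yaml(path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            [
                {"name": n, "formula": f, "group": g}
                for n, f, g in feature_catalogue()
            ],
            sort_keys=False,
        )
    )


def catalogue_from_yaml(path: str | Path) -> list[tuple[str, str, str]]:
    raw = yaml.safe_load(Path(path).read_text())
    return [(d["name"], d["formula"], d["group"]) for d in raw]


def _age_years(birth_ym: str, end_day_date: pd.Timestamp) -> float:
    """Completed years at the window-end date, from year-month of birth."""
    by, bm = (int(p) for p in birth_ym.split("-"))
    years = end_day_date.year - by
    if end_day_date.month < bm:
        years -= 1
    return float(years)


def extract_features(
    series: DailySeries,
    window: ObservationWindow,
    profile: dict,
) -> dict[str, float]:
    """Feature vector for one (user, window) pair.

    ``profile`` carries the user attributes: ``birth_ym`` (YYYY-MM) and
    ``sex`` in {male, female, unspecified}.  Deterministic; invariant to the
    ordering of input records (the series is day-sorted by construction).
    """
    if window.user_id != series.user_id:
        raise ValueError(
            f"window user {window.user_id!r} != series user {series.user_id!r}"
        )
    start, end = window.start_day, window.end_day
    days = series.days
    lo = np.searchsorted(days, start, side="left")
    hi = np.searchsorted(days, end, side="right")
    wdays = days[lo:hi]
    wcounts = series.counts[lo:hi]

    out: dict[str, float] = {}
    n_total = int(wcounts.sum())
    n_days = int(wdays.size)
    out["n_meas_total"] = float(n_total)
    out["n_days_measured"] = float(n_days)

    # history relative to the whole series
    j = np.searchsorted(days, end, side="right")
    out["days_since_last_meas"] = float(end - days[j - 1]) if j > 0 else float(
        end - series.first_day
    )
    out["days_since_first_meas"] = float(end - series.first_day)
    f0 = series.first_day
    k0 = np.searchsorted(days, f0, side="left")
    k1 = np.searchsorted(days, f0 + 13, side="right")
    out["n_meas_first14"] = float(series.counts[k0:k1].sum())

    # daily counts over the 14 window days (zeros included)
    daily = np.zeros(WINDOW_DAYS)
    daily[wdays - start] = wcounts
    out["daily_count_mean"] = float(daily.mean())
    out["daily_count_sd"] = float(daily.std(ddof=0))
    out["daily_count_max"] = float(daily.max())
    out["meas_per_measured_day"] = float(n_total / n_days) if n_days else np.nan

    # week decomposition; weekday/weekend from absolute day index (origin Monday)
    rel = wdays - start
    week2 = rel >= 7
    weekend = (wdays % 7) >= 5
    n_w1 = int(np.sum(~week2))
    n_w2 = int(np.sum(week2))
    out["n_days_week1"] = float(n_w1)
    out["n_days_week2"] = float(n_w2)
    out["delta_days_all"] = float(n_w2 - n_w1)
    out["delta_days_weekday"] = float(
        np.sum(week2 & ~weekend) - np.sum(~week2 & ~weekend)
    )
    out["delta_days_weekend"] = float(np.sum(week2 & weekend) - np.sum(~week2 & weekend))

    # streaks and in-window gaps
    measured = np.zeros(WINDOW_DAYS, dtype=bool)
    measured[rel] = True
    out["longest_streak"] = float(_longest_run(measured))
    out["max_gap_in_window"] = float(_longest_run(~measured))

    # vitals: per-reading statistics plus a least-squares slope of the
    # daily means against day index (needs >= 2 measured days)
    r_day, vitals, day_starts = series.reading_arrays()
    r_lo = np.searchsorted(r_day, start, side="left")
    r_hi = np.searchsorted(r_day, end, side="right")
    if wdays.size >= 2:
        rel_starts = day_starts[lo:hi] - r_lo
        x = wdays - wdays.mean()
        xx = float((x * x).sum())
    for v in _VITALS:
        vals = vitals[v][r_lo:r_hi]
        if vals.size == 0:
            for s in _VITAL_STATS:
                out[f"{v}_{s}"] = np.nan
            continue
        out[f"{v}_mean"] = float(vals.mean())
        out[f"{v}_sd"] = float(vals.std(ddof=0))
        out[f"{v}_min"] = float(vals.min())
        out[f"{v}_max"] = float(vals.max())
        out[f"{v}_last_minus_first"] = float(vals[-1] - vals[0])
        if wdays.size >= 2:
            means = np.add.reduceat(vals, rel_starts) / wcounts
            out[f"{v}_slope_per_day"] = float(
                (x * (means - means.mean())).sum() / xx
            )
        else:
            out[f"{v}_slope_per_day"] = np.nan

    # demographics
    end_date = _ORIGIN + pd.Timedelta(days=end)
    out["age_years"] = _age_years(str(profile["birth_ym"]), end_date)
    sex = str(profile["sex"])
    out["is_female"] = 1.0 if sex == "female" else 0.0
    out["sex_provided"] = 0.0 if sex == "unspecified" else 1.0
    return out


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def featurize_cohort(
    series_map: dict[str, DailySeries],
    windows: pd.DataFrame,
    users: pd.DataFrame,
) -> pd.DataFrame:
    """Feature matrix with one row per (user, window), catalogue column order.

    ``windows`` is the table produced by :func:`bpdropout.labeling.label_cohort`;
    ``users`` carries user_id, birth_ym, sex.
    """
    profiles = users.set_index("user_id")[["birth_ym", "sex"]].to_dict("index")
    rows = []
    for uid, start, end in zip(
        windows["user_id"], windows["start_day"], windows["end_day"]
    ):
        series = series_map[uid]
        w = ObservationWindow(uid, int(start), int(end))
        rows.append(extract_features(series, w, profiles[uid]))
    feat = pd.DataFrame(rows, columns=FEATURE_NAMES)
    out = pd.concat(
        [windows[["user_id", "start_day", "end_day"]].reset_index(drop=True), feat],
        axis=1,
    )
    return out
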