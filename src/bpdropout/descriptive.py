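"""Descriptive adherence analyses.

Companion summaries to the predictive models: the non-resumption curve (how
likely a gap of d consecutive unmeasured days is to never be followed by
confirmed resumption within 180 days), 180-day dropout rates by age band,
sex-stratified cumulative incidence of first dropout, a direct-standardised
two-regime comparison, calendar-monthly dropout rates, and the rank-sum
comparison of week-over-week measurement-day changes between continuing and
dropping users.

"Dropout" throughout means first onset of the inactive state: the first day
on which the trailing 28 days contain no measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import mannwhitneyu

from .config import CALENDAR_ORIGIN, DataError
from .labeling import DailySeries, GapEpisode, first_inactive_onset

logger = logging.getLogger(__name__)

AGE_BIN_EDGES = (18, 30, 40, 50, 60, 70, 80, np.inf)


def _age_bin_labels(edges=AGE_BIN_EDGES) -> list[str]:
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        out.append(f"{int(lo)}+" if np.isinf(hi) else f"{int(lo)}-{int(hi) - 1}")
    return out


@dataclass
class IncidenceCurve:
    """Cumulative probability of first dropout against days since first
    measurement (complement of the product-limit survival estimate)."""

    label: str
    times: np.ndarray
    values: np.ndarray
    at_risk: np.ndarray | None = field(default=None, repr=False)
    events: np.ndarray | None = field(default=None, repr=False)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Stepwise evaluation at arbitrary times."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        vals = np.concatenate([[0.0], self.values])
        return vals[idx + 1]


def non_resumption_curve(
    gaps: list[GapEpisode], d_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """P(no confirmed resumption within 180 days | gap length >= d).

    Episodes with undefined resumption status (insufficient follow-up) are
    excluded.  Points with an empty risk set carry rate NaN.
    """
    usable = [g for g in gaps if g.resumed_within_180 is not None]
    if d_grid is None:
        d_grid = np.arange(1, 61)
    lengths = np.array([g.gap_length for g in usable], dtype=int)
    not_resumed = np.array([not g.resumed_within_180 for g in usable], dtype=bool)
    rows = []
    for d in np.asarray(d_grid, dtype=int):
        at_risk = lengths >= d
        denom = int(at_risk.sum())
        num = int((at_risk & not_resumed).sum())
        rows.append(
            {
                "stratum": int(d),
                "numerator": num,
                "denominator": denom,
                "rate": num / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def dropout_rate_by_age(
    users: pd.DataFrame,
    series_map: dict[str, DailySeries],
    horizon: int = 180,
    age_bins: tuple[float, ...] = AGE_BIN_EDGES,
) -> pd.DataFrame:
    """Fraction of users whose first inactive state begins within ``horizon``
    days of their first measurement, per age band at first measurement.

    Only users with at least ``horizon`` days of follow-up count; empty bins
    are omitted with a warning.
    """
    labels = _age_bin_labels(age_bins)
    origin = pd.Timestamp(CALENDAR_ORIGIN)
    num = dict.fromkeys(labels, 0)
    den = dict.fromkeys(labels, 0)
    prof = users.set_index("user_id")["birth_ym"].to_dict()
    for uid, series in series_map.items():
        if not series.days.size:
            continue
        first = series.first_day
        if series.cutoff_day - first < horizon:
            continue
        first_date = origin + pd.Timedelta(days=first)
        by, bm = (int(p) for p in str(prof[uid]).split("-"))
        age = first_date.year - by - (first_date.month < bm)
        k = np.searchsorted(np.asarray(age_bins), age, side="right") - 1
        if k < 0 or k >= len(labels):
            continue
        onset = first_inactive_onset(series)
        den[labels[k]] += 1
        if onset is not None and onset <= first + horizon:
            num[labels[k]] += 1
    rows = []
    for lab in labels:
        if den[lab] == 0:
            logger.warning("age bin %s empty; omitted", lab)
            continue
        rows.append(
            {
                "stratum": lab,
                "numerator": num[lab],
                "denominator": den[lab],
                "rate": num[lab] / den[lab],
            }
        )
    return pd.DataFrame(rows)


def cumulative_incidence(
    event_times: np.ndarray,
    event_flags: np.ndarray,
    group_labels: np.ndarray | None = None,
) -> dict[str, IncidenceCurve]:
    """Product-limit cumulative incidence per group.

    ``event_times`` are days from first measurement to first dropout onset
    (flag 1) or censoring (flag 0).
    """
    t = np.asarray(event_times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    if np.any(t < 0):
        raise DataError("negative event times")
    if group_labels is None:
        group_labels = np.array(["all"] * t.size)
    g = np.asarray(group_labels)
    out: dict[str, IncidenceCurve] = {}
    for lab in pd.unique(g):
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
        et = kmf.event_table
        out[str(lab)] = IncidenceCurve(
            label=str(lab),
            times=times,
            values=1.0 - surv,
            at_risk=et["at_risk"].to_numpy(dtype=float),
            events=et["observed"].to_numpy(dtype=float),
        )
    return out


_DECADE_EDGES = (0, 30, 40, 50, 60, 70, 80, np.inf)


def _stratum_key(age: float, sex: str) -> str:
    k = np.searchsorted(np.asarray(_DECADE_EDGES), age, side="right") - 1
    lo, hi = _DECADE_EDGES[k], _DECADE_EDGES[k + 1]
    band = f"{int(lo)}+" if np.isinf(hi) else f"{int(lo)}-{int(hi) - 1}"
    return f"{band}|{sex}"


def standardized_incidence_comparison(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    time_grid: np.ndarray | None = None,
) -> tuple[IncidenceCurve, IncidenceCurve]:
    """Direct age-decade x sex standardisation of two cohorts' cumulative
    incidence, weighted by the pooled stratum distribution.

    Cohorts carry columns ``time``, ``event``, ``age_years``, ``sex``.
    Strata present in only one cohort are dropped from both (warned).
    """
    for name, c in (("A", cohort_a), ("B", cohort_b)):
        if c.empty:
            raise DataError(f"cohort {name} is empty")
    if time_grid is None:
        tmax = max(cohort_a["time"].max(), cohort_b["time"].max())
        time_grid = np.arange(0.0, float(tmax) + 1.0)
    time_grid = np.asarray(time_grid, dtype=float)

    def keyed(c: pd.DataFrame) -> pd.Series:
        return c.apply(lambda r: _stratum_key(r["age_years"], r["sex"]), axis=1)

    ka, kb = keyed(cohort_a), keyed(cohort_b)
    shared = sorted(set(ka) & set(kb))
    dropped = (set(ka) | set(kb)) - set(shared)
    if dropped:
        logger.warning("strata absent from one cohort dropped: %s", sorted(dropped))
    if not shared:
        raise DataError("no common strata between cohorts")
    weights = np.array([(ka == s).sum() + (kb == s).sum() for s in shared], dtype=float)
    weights /= weights.sum()

    def adjusted(c: pd.DataFrame, keys: pd.Series, label: str) -> IncidenceCurve:
        acc = np.zeros_like(time_grid)
        for s, w in zip(shared, weights):
            sub = c[(keys == s).to_numpy()]
            curves = cumulative_incidence(
                sub["time"].to_numpy(), sub["event"].to_numpy()
            )
            acc += w * curves["all"].at(time_grid)
        return IncidenceCurve(label=label, times=time_grid, values=acc)

    return adjusted(cohort_a, ka, "A"), adjusted(cohort_b, kb, "B")


def monthly_dropout_rate(
    series_map: dict[str, DailySeries],
    months: list[str] | None = None,
) -> pd.DataFrame:
    """Per calendar month: among users active at month start (a measurement
    in the preceding 28 days), the fraction whose first inactive state begins
    within the month."""
    if not series_map:
        return pd.DataFrame(columns=["stratum", "numerator", "denominator", "rate"])
    origin = pd.Timestamp(CALENDAR_ORIGIN)
    cutoff = max(s.cutoff_day for s in series_map.values())
    if months is None:
        last = origin + pd.Timedelta(days=cutoff)
        months = [
            str(p) for p in pd.period_range(origin.to_period("M"), last.to_period("M"))
        ]
    onsets = {uid: first_inactive_onset(s) for uid, s in series_map.items()}
    rows = []
    for m in months:
        p = pd.Period(m, freq="M")
        ms = (p.to_timestamp() - origin).days
        me = (p.to_timestamp(how="end").normalize() - origin).days
        if me > cutoff:
            continue
        denom = num = 0
        for uid, series in series_map.items():
            if not series.days.size or not series.has_measurement(ms - 28, ms - 1):
                continue
            denom += 1
            onset = onsets[uid]
            if onset is not None and ms <= onset <= me:
                num += 1
        rows.append(
            {
                "stratum": m,
                "numerator": num,
                "denominator": denom,
                "rate": num / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def dropout_event_table(series_map: dict[str, DailySeries]) -> pd.DataFrame:
    """Per-user time-to-first-dropout table for incidence estimation.

    ``time`` is days from first measurement to first inactive-state onset
    (event 1) or to the dataset cutoff (censored, event 0).
    """
    rows = []
    for uid, s in series_map.items():
        if not s.days.size:
            continue
        onset = first_inactive_onset(s)
        if onset is None:
            rows.append({"user_id": uid, "time": s.cutoff_day - s.first_day, "event": 0})
        else:
            rows.append({"user_id": uid, "time": onset - s.first_day, "event": 1})
    return pd.DataFrame(rows, columns=["user_id", "time", "event"])


@dataclass(frozen=True)
class RankSumComparison:
    scope: str
    statistic: float
    p_value: float
    median_continuation: float
    median_dropout: float
    n_continuation: int
    n_dropout: int


def compare_week_delta_by_outcome(
    features: pd.DataFrame, labels: np.ndarray, scope: str = "all"
) -> RankSumComparison:
    """Two-sided Mann-Whitney rank test of the week-2-minus-week-1
    measurement-day delta between continuing (label 0) and dropping
    (label 1) windows.  ``scope`` selects all days, weekdays or weekends."""
    col = {
        "all": "delta_days_all",
        "weekday": "delta_days_weekday",
        "weekend": "delta_days_weekend",
    }.get(scope)
    if col is None:
        raise DataError(f"unknown scope {scope!r}")
    labels = np.asarray(labels).astype(int)
    x = features[col].to_numpy(dtype=float)
    cont, drop = x[labels == 0], x[labels == 1]
    if cont.size == 0 or drop.size == 0:
        raise DataError("both outcome groups must be non-empty")
    stat, p = mannwhitneyu(cont, drop, alternative="two-sided")
    return RankSumComparison(
        scope=scope,
        statistic=float(stat),
        p_value=float(p),
        median_continuation=float(np.median(cont)),
        median_dropout=float(np.median(drop)),
        n_continuation=int(cont.size),
        n_dropout=int(drop.size),
    )
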