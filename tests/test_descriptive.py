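"""Non-resumption curve, incidence estimators, stratified rates, rank tests."""

import numpy as np
import pandas as pd
import pytest

from bpdropout import (
    DataError,
    compare_week_delta_by_outcome,
    cumulative_incidence,
    dropout_rate_by_age,
    monthly_dropout_rate,
    non_resumption_curve,
    standardized_incidence_comparison,
)
from bpdropout.labeling import GapEpisode

from ._oracles import brute_product_limit
from .conftest import make_series


def episode(length, resumed, uid="u"):
    return GapEpisode(uid, 100, length, 400, resumed)


class TestNonResumptionCurve:
    def test_all_resumed_is_zero(self):
        t = non_resumption_curve([episode(30, True)] * 5, d_grid=[1, 10, 28])
        assert (t["rate"] == 0).all()

    def test_none_resumed_is_one(self):
        t = non_resumption_curve([episode(30, False)] * 5, d_grid=[1, 10, 28])
        assert (t["rate"] == 1).all()

    def test_hand_counted_mixture(self):
        gaps = [episode(10, True), episode(30, False), episode(40, False)]
        t = non_resumption_curve(gaps, d_grid=[5, 28]).set_index("stratum")
        assert t.loc[5, "rate"] == pytest.approx(2 / 3)
        assert t.loc[28, "rate"] == 1.0

    def test_undefined_statuses_excluded_and_empty_risk_set_nan(self):
        gaps = [episode(10, True), episode(5, None)]
        t = non_resumption_curve(gaps, d_grid=[1, 50]).set_index("stratum")
        assert t.loc[1, "denominator"] == 1
        assert np.isnan(t.loc[50, "rate"])

    def test_monotone_in_gap_length_on_generated_data(self, study_series):
        from bpdropout import detect_gaps

        gaps = []
        for uid in list(study_series)[:1500]:
            gaps.extend(detect_gaps(study_series[uid]))
        usable = [g for g in gaps if g.resumed_within_180 is not None]
        assert len(usable) >= 1000
        t = non_resumption_curve(usable, d_grid=np.arange(1, 46))
        r = t["rate"].to_numpy()
        diffs = np.diff(r)
        # nested risk sets leave only O(1/denominator) jitter: no single
        # inversion nor the summed drawdown may exceed 0.02
        assert (diffs > -0.02).all()
        assert -diffs[diffs < 0].sum() <= 0.02


class TestCumulativeIncidence:
    def test_no_events_flat_zero(self):
        c = cumulative_incidence(np.arange(1, 6), np.zeros(5))["all"]
        assert np.allclose(c.values, 0)

    def test_hand_product_limit(self):
        c = cumulative_incidence(
            np.array([10, 15, 20, 25, 30]), np.array([1, 0, 1, 0, 1])
        )["all"]
        assert c.at(np.array([10]))[0] == pytest.approx(0.2, abs=1e-9)
        assert c.at(np.array([20]))[0] == pytest.approx(0.466666666667, abs=1e-9)
        assert c.at(np.array([30]))[0] == pytest.approx(1.0, abs=1e-9)

    def test_time_rescaling_invariance(self):
        t = np.array([3, 5, 8, 13.0])
        e = np.array([1, 0, 1, 1])
        a = cumulative_incidence(t, e)["all"]
        b = cumulative_incidence(2 * t, e)["all"]
        ev_a = a.values[np.isin(a.times, t)]
        ev_b = b.values[np.isin(b.times, 2 * t)]
        assert np.allclose(np.unique(ev_a), np.unique(ev_b))

    def test_negative_times_rejected(self):
        with pytest.raises(DataError):
            cumulative_incidence(np.array([-1.0, 2.0]), np.array([1, 1]))

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            t = rng.integers(1, 60, n).astype(float)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            curve = cumulative_incidence(t, e)["all"]
            times, inc = brute_product_limit(t, e)
            assert np.allclose(curve.at(times), inc, atol=1e-12)

    def test_curves_monotone_and_bounded(self):
        rng = np.random.default_rng(23)
        t = rng.integers(1, 300, 500).astype(float)
        e = rng.integers(0, 2, 500)
        g = rng.choice(["x", "y"], 500)
        for c in cumulative_incidence(t, e, g).values():
            assert np.all(np.diff(c.values) >= -1e-12)
            assert c.values.min() >= 0 and c.values.max() <= 1
            assert np.all(np.diff(c.at_risk) <= 0)


def cohort_frame(n, seed, hazard=0.01):
    rng = np.random.default_rng(seed)
    age = rng.uniform(25, 85, n)
    sex = rng.choice(["male", "female"], n)
    t = rng.geometric(hazard, n).astype(float)
    cens = rng.uniform(50, 400, n)
    event = (t <= cens).astype(int)
    time = np.minimum(t, cens)
    return pd.DataFrame({"time": time, "event": event, "age_years": age, "sex": sex})


class TestStandardizedComparison:
    def test_identical_cohorts_identical_curves(self):
        a = cohort_frame(300, 1)
        ca, cb = standardized_incidence_comparison(a, a.copy())
        assert np.allclose(ca.values, cb.values)

    def test_single_stratum_equals_crude(self):
        a = cohort_frame(200, 2)
        a["age_years"] = 45.0
        a["sex"] = "male"
        b = cohort_frame(150, 3)
        b["age_years"] = 45.0
        b["sex"] = "male"
        grid = np.arange(0, 200, 10.0)
        ca, cb = standardized_incidence_comparison(a, b, time_grid=grid)
        crude = cumulative_incidence(a["time"].to_numpy(), a["event"].to_numpy())["all"]
        assert np.allclose(ca.values, crude.at(grid))

    def test_no_common_strata_rejected(self):
        a = cohort_frame(50, 4)
        a["sex"] = "male"
        b = cohort_frame(50, 5)
        b["sex"] = "female"
        a["age_years"] = 35.0
        b["age_years"] = 75.0
        with pytest.raises(DataError):
            standardized_incidence_comparison(a, b)


class TestMonthlyRate:
    def test_nobody_drops(self):
        series = {f"u{i}": make_series(range(0, 200, 3), cutoff=210) for i in range(4)}
        t = monthly_dropout_rate(series)
        assert (t["rate"].dropna() == 0).all()

    def test_single_active_user_dropping(self):
        # measures through day 59, then silent; onset = day 87 (2018-03-29)
        series = {"u1": make_series(range(0, 60), cutoff=200)}
        t = monthly_dropout_rate(series).set_index("stratum")
        assert t.loc["2018-03", "rate"] == 1.0
        assert t.loc["2018-02", "rate"] == 0.0

    def test_numerators_bounded_by_denominators(self, study_series):
        sub = {u: study_series[u] for u in list(study_series)[:800]}
        t = monthly_dropout_rate(sub)
        ok = t["denominator"] > 0
        assert (t.loc[ok, "numerator"] <= t.loc[ok, "denominator"]).all()
        assert t.loc[ok, "rate"].between(0, 1).all()


class TestDropoutRateByAge:
    @staticmethod
    def users_for(series, birth="1970-01"):
        return pd.DataFrame(
            {"user_id": list(series), "birth_ym": birth, "sex": "male", "regime": "B"}
        )

    def test_daily_measurers_rate_zero(self):
        series = {f"u{i}": make_series(range(0, 200), cutoff=199, user_id=f"u{i}") for i in range(3)}
        t = dropout_rate_by_age(self.users_for(series), series)
        assert (t["rate"] == 0).all()

    def test_early_droppers_rate_one(self):
        series = {
            f"u{i}": make_series(range(0, 30), cutoff=299, user_id=f"u{i}")
            for i in range(3)
        }
        t = dropout_rate_by_age(self.users_for(series), series)
        assert (t["rate"] == 1).all()

    def test_planted_age_ushape(self, study_cohort, study_series):
        _, users, _, _ = study_cohort
        t = dropout_rate_by_age(users, study_series).set_index("stratum")
        mid = t.loc["60-69", "rate"]
        assert t.loc["18-29", "rate"] > mid or t.loc["30-39", "rate"] > mid
        assert t.loc["80+", "rate"] > mid


class TestWeekDeltaComparison:
    def test_identical_groups_high_p(self):
        f = pd.DataFrame({"delta_days_all": np.tile(np.arange(10.0), 4)})
        labels = np.repeat([0, 1], 20)
        res = compare_week_delta_by_outcome(f, labels, "all")
        assert res.p_value > 0.9
        assert res.median_continuation == res.median_dropout

    def test_disjoint_groups_tiny_p(self):
        f = pd.DataFrame(
            {"delta_days_weekday": np.concatenate([np.zeros(30), np.ones(30) * 5])}
        )
        labels = np.concatenate([np.ones(30), np.zeros(30)])
        res = compare_week_delta_by_outcome(f, labels, "weekday")
        assert res.p_value < 0.001

    def test_empty_group_rejected(self):
        f = pd.DataFrame({"delta_days_all": np.arange(5.0)})
        with pytest.raises(DataError):
            compare_week_delta_by_outcome(f, np.zeros(5), "all")
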