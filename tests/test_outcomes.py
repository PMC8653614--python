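"""Outcome computation: MMSE slopes, survival machinery, clinical utility."""

import numpy as np
import pandas as pd
import pytest

from adsubtypes import features
from adsubtypes.outcomes import (
    cox_hazard,
    km_estimate,
    log_rank,
    mmse_slopes,
    outcome_summary,
    utility_comparison,
)


def series(rows):
    return pd.DataFrame(rows, columns=["patient_id", "years_from_diagnosis", "score"])


class TestMMSESlopes:
    def test_two_point_line(self):
        s, _ = mmse_slopes(series([("P1", 0.0, 30.0), ("P1", 2.0, 24.0)]))
        assert s["P1"] == pytest.approx(-3.0)

    def test_single_visit_excluded(self):
        s, excluded = mmse_slopes(series([("P1", 0.0, 30.0),
                                          ("P2", 0.0, 28.0), ("P2", 1.0, 26.0)]))
        assert excluded == 1
        assert list(s.index) == ["P2"]

    def test_zero_time_span_excluded(self):
        s, excluded = mmse_slopes(series([("P1", 1.0, 30.0), ("P1", 1.0, 29.0)]))
        assert excluded == 1 and len(s) == 0


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        times = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        curve = km_estimate(times, np.ones(5, dtype=bool))
        for t in np.unique(times):
            ecdf = (times <= t).mean()
            surv = curve.loc[curve["time"] == t, "survival"].iloc[0]
            assert surv == pytest.approx(1 - ecdf, abs=1e-12)

    def test_hand_computed_censored_example(self):
        """Six subjects, times 6,6,6,7+,10,10+: S(6)=0.5, S(10)=0.25."""
        times = [6, 6, 6, 7, 10, 10]
        events = [True, True, True, False, True, False]
        curve = km_estimate(times, events).set_index("time")
        assert curve.loc[6, "survival"] == pytest.approx(0.5, abs=1e-12)
        assert curve.loc[10, "survival"] == pytest.approx(0.25, abs=1e-12)

    def test_no_events_warns_flat(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = km_estimate([1.0, 2.0], [False, False])
        assert (curve["survival"] == 1).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])


def _exponential_arms(rng, n, h0, h1, censor):
    t0 = rng.exponential(1 / h0, n)
    t1 = rng.exponential(1 / h1, n)
    times = np.concatenate([np.minimum(t0, censor), np.minimum(t1, censor)])
    events = np.concatenate([t0 <= censor, t1 <= censor])
    groups = np.repeat([0, 1], n)
    return times, events, groups


class TestLogRank:
    def test_identical_groups_null(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        events = np.ones(8, dtype=bool)
        groups = np.repeat([0, 1], 4)
        stat, p = log_rank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_single_event_time_matches_hypergeometric_closed_form(self):
        """One event time: the statistic reduces to (O-E)^2/V with the
        hypergeometric variance of the 2x2 risk table."""
        times = np.array([1.0] * 5 + [2.0] * 15)
        events = np.array([True] * 5 + [False] * 15)
        groups = np.array([0] * 4 + [1] * 1 + [0] * 6 + [1] * 9)
        d, n = 5, 20
        n0 = 10
        e0 = d * n0 / n
        v = d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
        expected = (4 - e0) ** 2 / v
        stat, _ = log_rank(times, events, groups)
        assert stat == pytest.approx(expected, rel=1e-10)

    def test_power_at_hazard_ratio_three(self, rng):
        rejections = 0
        reps = 20
        for _ in range(reps):
            times, events, groups = _exponential_arms(rng, 250, 0.1, 0.3, 8.0)
            _, p = log_rank(times, events, groups)
            rejections += p < 0.05
        assert rejections >= 0.95 * reps

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [True, True], [0, 0])


class TestCox:
    def test_hazard_ratio_recovery(self, rng):
        times, events, groups = _exponential_arms(rng, 1000, 0.1, 0.2, 10.0)
        res = cox_hazard(pd.Series(groups.astype(float), name="arm"),
                         times, events)
        hr = res.hazard_ratios["arm"]
        assert 1.8 <= hr <= 2.2
        assert res.ci_lower["arm"] < hr < res.ci_upper["arm"]

    def test_null_covariate_ci_covers_one(self, rng):
        covered = 0
        reps = 20
        for _ in range(reps):
            t = rng.exponential(5.0, 300)
            e = t < 8.0
            t = np.minimum(t, 8.0)
            x = rng.integers(0, 2, 300).astype(float)
            res = cox_hazard(pd.Series(x, name="x"), t, e)
            covered += res.ci_lower["x"] <= 1.0 <= res.ci_upper["x"]
        assert covered >= 0.8 * reps

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_hazard(pd.Series([0.0, 1.0], name="x"), [1.0, 2.0],
                       [False, False])

    def test_separation_flagged_not_raised(self):
        x = pd.Series([0.0] * 10 + [1.0] * 10, name="x")
        times = np.array([5.0] * 10 + [0.1] * 10)
        events = np.array([False] * 10 + [True] * 10)
        res = cox_hazard(x, times, events)
        assert res.flagged or res.ci_upper["x"] > 100


def _toy_features(n, rng):
    vals = pd.DataFrame({
        "memory": rng.integers(0, 2, n),
        "depression": rng.integers(0, 2, n),
    }, index=[f"P{i}" for i in range(n)])
    meta = pd.DataFrame(
        {"parent": ["memory", "depression"], "role": ["symptom", "comorbidity"]},
        index=pd.Index(["memory", "depression"], name="column"),
    )
    return features.FeatureMatrix(values=vals, meta=meta)


class TestUtilityComparison:
    def _outcomes(self, n, slopes, rng):
        return pd.DataFrame({
            "mmse_slope": slopes,
            "time_to_assisted_living": rng.exponential(5.0, n),
            "assisted_living_event": rng.random(n) < 0.7,
        }, index=[f"P{i}" for i in range(n)])

    def test_cluster_equal_to_feature_ties_r2(self, rng):
        n = 300
        fm = _toy_features(n, rng)
        labels = fm.values["depression"].to_numpy()
        slopes = -1.0 - 2.0 * labels + rng.normal(0, 0.3, n)
        out = self._outcomes(n, slopes, rng)
        rep = utility_comparison(fm, labels, out)
        assert rep.table.loc["cluster membership", "adjusted_r2"] == pytest.approx(
            rep.table.loc["depression", "adjusted_r2"], abs=1e-12)

    def test_class_generated_outcome_ranks_cluster_first(self, rng):
        n = 400
        fm = _toy_features(n, rng)
        labels = rng.integers(0, 3, n)
        slopes = -np.array([1.0, 2.0, 3.0])[labels] + rng.normal(0, 0.2, n)
        t = rng.exponential(1 / np.array([0.1, 0.25, 0.5])[labels])
        out = pd.DataFrame({
            "mmse_slope": slopes,
            "time_to_assisted_living": np.minimum(t, 8.0),
            "assisted_living_event": t <= 8.0,
        }, index=fm.values.index)
        rep = utility_comparison(fm, labels, out)
        assert rep.cluster_top_r2
        assert rep.cluster_top_cox

    def test_pure_noise_outcome_near_zero_r2(self, rng):
        n = 5000
        fm = _toy_features(n, rng)
        labels = rng.integers(0, 3, n)
        out = self._outcomes(n, rng.normal(0, 1, n), rng)
        rep = utility_comparison(fm, labels, out)
        assert (rep.table["adjusted_r2"].abs() < 0.01).all()

    def test_relabeling_invariance_of_cluster_r2(self, rng):
        n = 300
        fm = _toy_features(n, rng)
        labels = rng.integers(0, 3, n)
        slopes = -np.array([1.0, 2.0, 3.0])[labels] + rng.normal(0, 0.2, n)
        out = self._outcomes(n, slopes, rng)
        a = utility_comparison(fm, labels, out)
        b = utility_comparison(fm, (labels + 1) % 3, out)
        assert a.table.loc["cluster membership", "adjusted_r2"] == pytest.approx(
            b.table.loc["cluster membership", "adjusted_r2"], abs=1e-10)


class TestOutcomeSummary:
    def _table(self, n, rng, rate=4.0):
        return pd.DataFrame({
            "consultations_per_year": rng.poisson(rate, n).astype(float),
            "missed_per_year": rng.poisson(0.4, n).astype(float),
            "chei_duration": rng.normal(2.0, 0.5, n),
            "mmse_slope": rng.normal(-1.5, 0.5, n),
            "time_to_death": rng.exponential(5.0, n),
            "death_event": rng.random(n) < 0.5,
            "time_to_assisted_living": rng.exponential(4.0, n),
            "assisted_living_event": rng.random(n) < 0.5,
        }, index=[f"P{i}" for i in range(n)])

    def test_single_cluster_equals_cohort_summary(self, rng):
        tab = self._table(100, rng)
        summ = outcome_summary(tab, np.zeros(100, dtype=int))
        m = summ.means.set_index("outcome")
        assert m.loc["chei_duration", "mean"] == pytest.approx(
            tab["chei_duration"].mean())
        assert summ.pairwise_logrank.empty

    def test_poisson_rate_separation_disjoint_cis(self, rng):
        a = self._table(500, rng, rate=4.0)
        b = self._table(500, rng, rate=8.0)
        tab = pd.concat([a, b])
        tab.index = [f"Q{i}" for i in range(1000)]
        labels = np.repeat([0, 1], 500)
        summ = outcome_summary(tab, labels)
        rows = summ.means[summ.means["outcome"] == "consultations_per_year"]
        lo = rows.set_index("cluster")
        assert lo.loc[0, "ci_upper"] < lo.loc[1, "ci_lower"]

    def test_constant_durations_zero_width_ci(self, rng):
        tab = self._table(50, rng)
        tab["chei_duration"] = 2.5
        summ = outcome_summary(tab, np.repeat([0, 1], 25))
        rows = summ.means[summ.means["outcome"] == "chei_duration"]
        assert (rows["ci_upper"] - rows["ci_lower"] == 0).all()
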