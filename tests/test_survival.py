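"""Kaplan-Meier, log-rank and Cox wrappers against hand-enumerable oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from ecsubtype import cox_ph, curve_summary, km_estimate, logrank_test
from ecsubtype.survival import DegenerateInputError, group_survival_report


def km_oracle(times, events):
    """Direct product-limit over risk sets (independent of the wrapped fit)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out[t] = s
    return out


def logrank_oracle_2group(times, events, groups):
    """Two-group log-rank chi-square by direct O-E / V enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKM:
    def test_all_censored_curve_is_flat_at_one(self):
        curve = km_estimate([5, 8, 12], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(120) == 1.0

    def test_no_censoring_closed_form(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert curve.s_hat == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_mixed_censoring_matches_hand_enumeration(self):
        times = [1, 2, 3, 4, 4, 5, 6, 7]
        events = [1, 0, 1, 1, 0, 1, 0, 1]
        oracle = km_oracle(times, events)
        # frozen values from the oracle: 7/8, 35/48, 7/12, 7/18, 0
        assert oracle == pytest.approx(
            {1.0: 7 / 8, 3.0: 35 / 48, 4.0: 7 / 12, 5.0: 7 / 18, 7.0: 0.0}
        )
        curve = km_estimate(times, events)
        assert dict(zip(curve.event_times, curve.s_hat)) == pytest.approx(oracle)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 40).round(2)
        events = np.ones(40, int)
        curve = km_estimate(times, events)
        for t, s in zip(curve.event_times, curve.s_hat):
            assert s == pytest.approx(np.mean(times > t))

    def test_ci_bounds_bracket_estimate(self):
        curve = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        assert np.all(curve.ci_low <= curve.s_hat + 1e-12)
        assert np.all(curve.s_hat <= curve.ci_high + 1e-12)

    def test_converting_event_to_censoring_never_lowers_later_survival(self):
        times = [1, 2, 3, 4, 5]
        with_event = km_estimate(times, [1, 1, 1, 1, 1])
        censored = km_estimate(times, [1, 0, 1, 1, 1])
        for t in (3, 4, 5, 10):
            assert censored.survival_at(t) >= with_event.survival_at(t) - 1e-12

    def test_empty_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestCurveSummary:
    def test_event_free_group_has_full_rate(self):
        curve = km_estimate([50, 80, 100], [0, 0, 0])
        summary = curve_summary(curve, 120)
        assert summary["rate_at_horizon"] == 1.0
        assert summary["median_months"] is None

    def test_median_at_exact_half_crossing(self):
        # 2 deaths at t=35 out of 4 -> S(35) = 0.5 exactly
        curve = km_estimate([35, 35, 40, 50], [1, 1, 0, 0])
        assert curve_summary(curve)["median_months"] == 35

    def test_median_not_reached_above_half(self):
        curve = km_estimate([10, 20, 30, 40], [1, 0, 0, 0])
        assert curve_summary(curve)["median_months"] is None


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = logrank_test(times, events, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_two_group_matches_hand_enumeration(self):
        times = [2, 4, 5, 7, 8, 1, 3, 3, 6, 9]
        events = [1, 1, 0, 1, 1, 1, 1, 0, 1, 1]
        groups = ["a"] * 5 + ["b"] * 5
        res = logrank_test(times, events, groups)
        assert res.chi2 == pytest.approx(logrank_oracle_2group(times, events, groups))

    def test_invariant_under_group_relabeling(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(20, 60)
        events = rng.integers(0, 2, 60)
        groups = rng.choice(["x", "y", "z"], 60)
        relabeled = np.array([{"x": "c", "y": "a", "z": "b"}[g] for g in groups])
        r1 = logrank_test(times, events, groups)
        r2 = logrank_test(times, events, relabeled)
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.df == r2.df == 2

    def test_complete_separation_is_highly_significant(self):
        times = list(np.linspace(1, 5, 25)) + list(np.linspace(50, 90, 25))
        events = [1] * 50
        groups = ["early"] * 25 + ["late"] * 25
        assert logrank_test(times, events, groups).p_value < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def test_recovers_planted_binary_effect(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.integers(0, 2, n)
        lam = 0.02 * np.exp(math.log(2) * x)
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 180, n)
        events = (t_event <= t_cens).astype(int)
        res = cox_ph(pd.DataFrame({"x": x}), np.minimum(t_event, t_cens), events)
        assert res.converged
        assert res.table.loc["x", "log_hr"] == pytest.approx(math.log(2), abs=0.1)
        assert res.table.loc["x", "ci95_low"] < res.table.loc["x", "hr"] \
            < res.table.loc["x", "ci95_high"]

    def test_sign_agrees_with_km_ordering(self):
        rng = np.random.default_rng(10)
        n = 300
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.02 * np.exp(0.9 * x)))
        res = cox_ph(pd.DataFrame({"x": x}), t, np.ones(n, int))
        km0 = km_estimate(t[x == 0], np.ones((x == 0).sum(), int))
        km1 = km_estimate(t[x == 1], np.ones((x == 1).sum(), int))
        assert res.table.loc["x", "log_hr"] > 0
        assert km1.survival_at(60) < km0.survival_at(60)

    def test_null_covariate_ci_covers_one(self):
        """Permuted covariate: 95% Wald CI covers HR=1 in ~95% of replicates."""
        rng = np.random.default_rng(7)
        n = 120
        covered = 0
        reps = 200
        for _ in range(reps):
            x = rng.integers(0, 2, n)
            t = rng.exponential(30, n)  # hazard independent of x
            res = cox_ph(pd.DataFrame({"x": x}), t, np.ones(n, int))
            covered += res.table.loc["x", "ci95_low"] <= 1.0 <= res.table.loc["x", "ci95_high"]
        assert 0.91 <= covered / reps <= 0.99

    def test_constant_covariate_rejected(self):
        with pytest.raises(DegenerateInputError):
            cox_ph(pd.DataFrame({"x": [0, 0, 0, 0]}), [1, 2, 3, 4], [1, 1, 1, 1])

    def test_breslow_ties_available(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 100)
        t = rng.integers(1, 10, 100).astype(float)  # heavy ties
        res = cox_ph(pd.DataFrame({"x": x}), t, np.ones(100, int), ties_method="breslow")
        assert res.ties_method == "breslow"
        assert np.isfinite(res.table.loc["x", "log_hr"])


def test_group_report_shape(small_cohort):
    from ecsubtype.classifier import classify_cohort

    labels = classify_cohort(small_cohort)
    clin = small_cohort.clinical_frame()
    report = group_survival_report(
        clin["os_months"].astype(float),
        clin["os_event"].astype(int),
        [labels[s].value for s in small_cohort.sample_ids],
    )
    assert set(report.columns) == {"group", "n", "events", "rate_at_120m", "median_months"}
    assert report["n"].sum() == len(small_cohort)
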