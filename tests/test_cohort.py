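"""Cohort statistics against independent oracles and small worked examples."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from aquascore import (
    CohortSimParams,
    adjust_batch,
    assign_groups,
    binary_endpoint,
    compare_methods_auroc,
    cox_fit,
    cross_classify,
    km_logrank,
    optimal_cutoff,
    ph_diagnostic,
    quantile_groups,
    reclassification_analysis,
    simulate_cohort,
)
from aquascore.types import ConfigurationError


class TestAdjustBatch:
    def test_single_batch_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(adjust_batch(x, ["a", "a", "a"]), x)

    def test_pure_location_effect_removed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(50, 5, 40)
        b = a + 10.0
        x = np.concatenate([a, b])
        batch = np.array(["A"] * 40 + ["B"] * 40)
        adj = adjust_batch(x, batch)
        assert abs(adj[batch == "A"].mean() - adj[batch == "B"].mean()) < 1e-9

    def test_affine_distortion_recovered(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(40, 12, 300)
        batch = np.array(["A", "B", "C"])[rng.integers(0, 3, 300)]
        shift = {"A": 0.0, "B": 10.0, "C": -6.0}
        scale = {"A": 1.0, "B": 1.5, "C": 0.7}
        distorted = np.array([truth[i] * scale[b] + shift[b]
                              for i, b in enumerate(batch)])
        adj = adjust_batch(distorted, batch)
        # equal per-batch moments after adjustment
        means = [adj[batch == b].mean() for b in "ABC"]
        sds = [adj[batch == b].std(ddof=1) for b in "ABC"]
        assert np.ptp(means) / np.mean(means) < 1e-6
        assert np.ptp(sds) / np.mean(sds) < 1e-6
        assert np.corrcoef(adj, truth)[0, 1] > 0.99

    def test_within_batch_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        batch = np.repeat(["A", "B"], 30)
        adj = adjust_batch(x, batch)
        for b in "AB":
            sel = batch == b
            assert np.array_equal(np.argsort(x[sel]), np.argsort(adj[sel]))

    def test_singleton_batch_errors(self):
        with pytest.raises(ConfigurationError, match="lonely|batch"):
            adjust_batch([1.0, 2.0, 3.0], ["A", "A", "lonely"])


def _brute_force_cutoff(scores, outcome):
    """Exhaustive threshold enumeration maximizing Youden's J, computed in
    exact rational arithmetic (ties -> lowest threshold)."""
    from fractions import Fraction

    best = None
    n_pos = int(np.sum(outcome == 1))
    n_neg = int(np.sum(outcome == 0))
    for t in sorted(set(scores)):
        pred = scores >= t
        sens = Fraction(int(np.sum(pred[outcome == 1])), n_pos)
        spec = Fraction(int(np.sum(~pred[outcome == 0])), n_neg)
        j = sens + spec - 1
        if best is None or j > best[0]:
            best = (j, t, sens, spec)
    return best


class TestOptimalCutoff:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        outcome = np.array([0, 0, 1, 1])
        res = optimal_cutoff(scores, outcome)
        assert res.auroc == pytest.approx(1.0)
        assert 0.2 < res.cutoff <= 0.8
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(10, 60)
            scores = np.round(rng.random(n) * 10, 2)
            outcome = rng.integers(0, 2, n)
            if outcome.min() == outcome.max():
                continue
            res = optimal_cutoff(scores, outcome)
            j, t, sens, spec = _brute_force_cutoff(scores, outcome)
            assert res.cutoff == pytest.approx(t)
            assert res.sensitivity + res.specificity - 1 == pytest.approx(float(j))

    def test_auroc_matches_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(20, 100)
            scores = rng.random(n)
            outcome = rng.integers(0, 2, n)
            if outcome.min() == outcome.max():
                continue
            res = optimal_cutoff(scores, outcome)
            assert res.auroc == pytest.approx(roc_auc_score(outcome, scores))

    def test_independent_score_auroc_half(self):
        rng = np.random.default_rng(6)
        scores = rng.random(4000)
        outcome = rng.integers(0, 2, 4000)
        res = optimal_cutoff(scores, outcome)
        assert abs(res.auroc - 0.5) < 0.03

    def test_single_class_errors(self):
        with pytest.raises(ConfigurationError):
            optimal_cutoff([1.0, 2.0], [1, 1])

    def test_two_gaussian_recovery(self):
        """Outcome-linked membership in N(30,5) vs N(50,5): the Youden
        cutoff lands near the midpoint."""
        cutoffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            member = rng.random(200) < 0.4
            scores = np.where(member, rng.normal(50, 5, 200), rng.normal(30, 5, 200))
            res = optimal_cutoff(scores, member.astype(int))
            cutoffs.append(res.cutoff)
        assert 35 <= np.mean(cutoffs) <= 45


class TestAssignGroups:
    def test_boundary_is_high(self):
        assert assign_groups([41.47], 41.47)[0] == "high"

    def test_all_below(self):
        assert (assign_groups([1.0, 2.0], 10.0) == "low").all()

    def test_bimodal_agreement_with_truth(self):
        rng = np.random.default_rng(7)
        member = rng.random(500) < 0.4
        scores = np.where(member, rng.normal(55, 8, 500), rng.normal(30, 7, 500))
        groups = assign_groups(scores, 42.5)
        agreement = np.mean((groups == "high") == member)
        assert agreement >= 0.95

    def test_nonfinite_cutoff(self):
        with pytest.raises(ConfigurationError):
            assign_groups([1.0], np.nan)


def _brute_logrank(times, events, groups):
    """Direct O-E computation of the two-group log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = np.sum((times == t) & (events == 1))
        n = at_risk.sum()
        n1 = np.sum(at_risk & (groups == labels[0]))
        d1 = np.sum((times == t) & (events == 1) & (groups == labels[0]))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKMLogrank:
    def test_no_censoring_equals_empirical_survivor(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.ones(5, dtype=int)
        res = km_logrank(times, events, ["g"] * 5)
        curve = res.km_curves["g"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx(np.mean(times > t))

    def test_worked_product_limit_with_censoring(self):
        # 6 subjects: deaths at 1, 3, 4, 6; censored at 2 and 5.
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 0, 1, 1, 0, 1]
        res = km_logrank(times, events, ["g"] * 6)
        curve = res.km_curves["g"].set_index("time")["survival"]
        assert curve.loc[1] == pytest.approx(5 / 6)
        assert curve.loc[3] == pytest.approx(5 / 6 * 3 / 4)
        assert curve.loc[4] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert curve.loc[6] == pytest.approx(0.0)

    def test_identical_groups_zero_statistic(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        events = np.tile([1, 0, 1, 1], 2)
        groups = np.repeat(["a", "b"], 4)
        res = km_logrank(times, events, groups)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-10)
        assert res.logrank_p == pytest.approx(1.0)

    def test_statistic_matches_direct_o_minus_e(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 40).round(1) + 0.1
        events = rng.integers(0, 2, 40)
        groups = np.repeat(["a", "b"], 20)
        if events.sum() == 0:
            events[0] = 1
        res = km_logrank(times, events, groups)
        assert res.logrank_stat == pytest.approx(
            _brute_logrank(times, events, groups), rel=1e-6
        )

    def test_empty_group_errors(self):
        with pytest.raises(ConfigurationError):
            km_logrank([1.0], [1], [])


def _partial_likelihood(beta, times, events, x):
    """Breslow partial log-likelihood (no ties in the test data)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_tiny_dataset_matches_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_fit(pd.DataFrame({"x": x}), times, events, "univariate")
        grid = np.linspace(-3, 3, 6001)
        lls = [_partial_likelihood(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert res.cox_summary["log_hr"].iloc[0] == pytest.approx(best, abs=2e-3)

    def test_null_large_n_hr_near_one(self):
        rng = np.random.default_rng(9)
        n = 2000
        times = rng.exponential(10, n)
        events = np.ones(n, dtype=int)
        x = rng.integers(0, 2, n).astype(float)
        res = cox_fit(pd.DataFrame({"x": x}), times, events, "univariate")
        assert abs(res.cox_summary["log_hr"].iloc[0]) < 0.15

    def test_recovers_true_hr(self):
        params = CohortSimParams(n_patients=2000, true_log_hr_myc=0.0,
                                 true_log_hr_ipi=0.0, seed=10)
        _, clinical, truth = simulate_cohort(params)
        cov = pd.DataFrame({"bcl2": truth.patients["true_high_bcl2"].astype(float)})
        res = cox_fit(cov, clinical["os_months"], clinical["os_event"], "multivariate")
        row = res.cox_summary.iloc[0]
        assert row["ci_lower"] <= 2.0 <= row["ci_upper"]
        assert abs(row["log_hr"] - np.log(2.0)) < 0.2

    def test_univariate_fits_each_covariate_alone(self):
        rng = np.random.default_rng(11)
        n = 200
        cov = pd.DataFrame({"a": rng.integers(0, 2, n).astype(float),
                            "b": rng.normal(size=n)})
        times = rng.exponential(10, n)
        events = np.ones(n, dtype=int)
        uni = cox_fit(cov, times, events, "univariate")
        assert set(uni.cox_summary["covariate"]) == {"a", "b"}
        solo = cox_fit(cov[["a"]], times, events, "multivariate")
        a_row = uni.cox_summary.set_index("covariate").loc["a", "log_hr"]
        assert a_row == pytest.approx(solo.cox_summary["log_hr"].iloc[0])

    def test_constant_covariate_errors(self):
        with pytest.raises(ConfigurationError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}),
                    [1, 2, 3], [1, 1, 1], "multivariate")


class TestPHDiagnostic:
    def test_exact_ph_parallel(self):
        rng = np.random.default_rng(12)
        n = 2000
        t1 = rng.exponential(10, n)
        t2 = rng.exponential(5, n)  # proportional: constant hazard ratio 2
        times = np.concatenate([t1, t2])
        events = np.ones(2 * n, dtype=int)
        groups = np.repeat(["a", "b"], n)
        res = ph_diagnostic(times, events, groups)
        assert res.ph_gap_sd is not None
        assert res.ph_gap_sd < 0.1

    def test_crossing_hazards_large_gap_sd(self):
        rng = np.random.default_rng(13)
        n = 1000
        # group a: tight around 10; group b: bimodal early/late -> crossing
        t_a = rng.normal(10, 1, n).clip(0.1)
        t_b = np.concatenate([rng.normal(2, 0.3, n // 2),
                              rng.normal(30, 3, n - n // 2)]).clip(0.1)
        times = np.concatenate([t_a, t_b])
        events = np.ones(2 * n, dtype=int)
        groups = np.repeat(["a", "b"], n)
        res = ph_diagnostic(times, events, groups)
        assert res.ph_gap_sd > 0.5

    def test_group_without_events_omitted(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 0]
        groups = ["a", "a", "b", "b"]
        res = ph_diagnostic(times, events, groups)
        assert "b" not in res.ph_curves
        assert any("no events" in w for w in res.notes)

    def test_single_event_degenerate(self):
        res = ph_diagnostic([1.0, 2.0], [1, 1], ["a", "b"])
        assert res.ph_gap_sd is None


class TestQuantileGroups:
    def test_scores_1_to_100(self):
        groups = quantile_groups(np.arange(1.0, 101.0))
        counts = pd.Series(groups).value_counts()
        assert counts["Q1"] == 10
        assert counts["Q2"] == 40
        assert counts["Q3"] == 40
        assert counts["Q4"] == 10

    def test_all_equal_errors(self):
        with pytest.raises(ConfigurationError):
            quantile_groups(np.full(20, 3.0))

    def test_monotone_hazard_gives_monotone_group_hrs(self):
        rng = np.random.default_rng(14)
        n = 3000
        score = rng.uniform(0, 100, n)
        times = rng.exponential(1.0 / (0.01 * np.exp(0.02 * score)))
        events = np.ones(n, dtype=int)
        groups = quantile_groups(score)
        cov = pd.get_dummies(pd.Series(groups, name="q"), drop_first=True, dtype=float)
        res = cox_fit(cov, times, events, "multivariate")
        hrs = res.cox_summary.set_index("covariate")["hr"]
        assert hrs["Q2"] < hrs["Q3"] < hrs["Q4"]


class TestCrossClassify:
    def test_joint_labels(self):
        out = cross_classify(["high", "low"], ["high", "high"])
        assert list(out) == ["high/high", "low/high"]

    def test_independent_prevalences(self):
        rng = np.random.default_rng(15)
        n = 20000
        b = np.where(rng.random(n) < 0.39, "high", "low")
        m = np.where(rng.random(n) < 0.25, "high", "low")
        out = cross_classify(b, m)
        frac = np.mean(out == "high/high")
        assert abs(frac - 0.39 * 0.25) < 0.01

    def test_mismatched_ids_error(self):
        with pytest.raises(ConfigurationError):
            cross_classify(["high"], ["low"], patient_ids=["a", "a"])


class TestReclassification:
    def test_identical_classifications(self):
        conv = np.array([True, True, False, False])
        aqua = np.array(["high", "high", "low", "low"])
        out = reclassification_analysis(conv, aqua, [1, 2, 3, 4], [1, 1, 1, 1])
        assert out["table"]["conventional_high_aqua_low"] == 0
        assert out["table"]["conventional_low_aqua_high"] == 0
        assert out["within_stratum"] == {}
        assert len(out["warnings"]) == 2

    def test_toy_discordance_counts(self):
        conv = np.array([True] * 6 + [False] * 4)
        aqua = np.array(["high"] * 3 + ["low"] * 3 + ["low"] * 3 + ["high"])
        out = reclassification_analysis(conv, aqua, np.arange(10.0), np.ones(10, int))
        assert out["table"] == {
            "conventional_high_aqua_high": 3,
            "conventional_high_aqua_low": 3,
            "conventional_low_aqua_high": 1,
            "conventional_low_aqua_low": 3,
        }

    def test_reclassified_low_patients_survive_longer(self):
        """When AQUA tracks true risk but the conventional call ignores
        intensity, conventional-high/AQUA-low patients outlive
        conventional-high/AQUA-high patients."""
        rng = np.random.default_rng(16)
        n = 600
        high_risk = rng.random(n) < 0.4
        aqua = np.where(high_risk, "high", "low")
        conv = rng.random(n) < 0.7  # proportion-driven, risk-blind
        times = rng.exponential(np.where(high_risk, 5.0, 15.0))
        events = np.ones(n, dtype=int)
        out = reclassification_analysis(conv, aqua, times, events)
        stratum = out["within_stratum"]["conventional_high"]
        assert stratum["mean_time_aqua_low"] > stratum["mean_time_aqua_high"]
        assert stratum["logrank_p"] < 0.05


class TestCompareMethods:
    def test_perfect_score(self):
        y = np.array([0, 1] * 20)
        out = compare_methods_auroc({"m": y.astype(float)}, y, n_boot=50)
        assert out["auroc"].iloc[0] == pytest.approx(1.0)

    def test_independent_score_half(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 3000)
        x = rng.random(3000)
        out = compare_methods_auroc({"m": x}, y, n_boot=20)
        assert abs(out["auroc"].iloc[0] - 0.5) < 0.03

    def test_negation_symmetry(self):
        rng = np.random.default_rng(18)
        y = rng.integers(0, 2, 200)
        x = rng.random(200) + 0.3 * y
        out = compare_methods_auroc({"pos": x, "neg": -x}, y, n_boot=20)
        a = out.set_index("method")["auroc"]
        assert a["neg"] == pytest.approx(1.0 - a["pos"], abs=1e-9)

    def test_ci_contains_point(self):
        rng = np.random.default_rng(19)
        y = rng.integers(0, 2, 300)
        x = rng.random(300) + 0.5 * y
        out = compare_methods_auroc({"m": x}, y, n_boot=200, seed=1).iloc[0]
        assert out["ci_lower"] <= out["auroc"] <= out["ci_upper"]


class TestBinaryEndpoint:
    def test_os_5y_rules(self):
        clinical = pd.DataFrame({
            "os_months": [10.0, 70.0, 30.0, 80.0],
            "os_event": [1, 1, 0, 0],
            "efs_months": [10.0, 60.0, 30.0, 80.0],
            "efs_event": [1, 1, 0, 0],
        })
        evaluable, outcome, definition = binary_endpoint(clinical, "os_5y")
        # censored at 30 months is not evaluable for 5-year status
        np.testing.assert_array_equal(evaluable, [True, True, False, True])
        np.testing.assert_array_equal(outcome, [1, 0, 0])
        assert "5 years" in definition

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            binary_endpoint(pd.DataFrame(), "nope")
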