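"""Outcome classification and the two-sample statistical engine."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from csfpulse import (
    CohortSpec,
    SummaryStats,
    ccos_improved,
    classify_relief,
    compare_cohort,
    generate_cohort,
    improvement_rate,
    ks_normality,
    mann_whitney,
    summary_stats,
    t_test_samples,
    t_test_summary,
    threshold_exclusivity,
)
from csfpulse.stats import ThresholdRule


class TestOutcomeDefinitions:
    @pytest.mark.parametrize(
        "pre,post,qol,expected",
        [
            (7, 4, True, True),   # reduction 3 > 2
            (7, 5, True, False),  # reduction exactly 2: not relieved
            (8, 2, False, False),  # no QoL improvement
        ],
    )
    def test_relief_definition(self, pre, post, qol, expected):
        assert classify_relief(pre, post, qol) is expected

    @pytest.mark.parametrize("ccos,expected", [(13, True), (12, False), (16, True), (4, False)])
    def test_ccos_improvement_band(self, ccos, expected):
        assert ccos_improved(ccos) is expected

    def test_ccos_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ccos_improved(17)

    def test_improvement_rate_rounding(self):
        assert improvement_rate([True] * 38 + [False] * 3) == 92.7
        assert improvement_rate([False] * 10) == 0.0
        assert improvement_rate([True] * 4 + [False] * 8) == 33.3


class TestKSNormality:
    def test_exact_quantile_sample_distance(self):
        # sample at the (i - 0.5)/n standard-normal quantiles, tested against
        # the generating N(0,1): D = 0.5/n exactly
        n = 20
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d, _ = ks_normality(x, mean=0.0, sd=1.0)
        assert d == pytest.approx(0.5 / n, abs=1e-12)

    def test_distance_bounded(self):
        rng = np.random.default_rng(0)
        d, p = ks_normality(rng.normal(5, 2, 50))
        assert 0.0 <= d <= 1.0
        assert 0.0 <= p <= 1.0

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-5, 0.3, 25), rng.normal(5, 0.3, 25)])
        _, p = ks_normality(x)
        assert p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.full(10, 3.0))


class TestTTests:
    def test_identical_groups(self):
        a = SummaryStats(10, 5.0, 1.0)
        res = t_test_summary(a, a)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_equal_groups_defined(self):
        a = SummaryStats(5, 2.0, 0.0)
        assert t_test_summary(a, a).p_value == 1.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ((12, 65.0, 45.0), (29, 32.0, 24.0)),
            ((12, 485.0, 163.0), (29, 613.0, 166.0)),
            ((12, 334.0, 262.0), (29, 410.0, 172.0)),
        ],
    )
    @pytest.mark.parametrize("variant", ["welch", "student"])
    def test_matches_scipy_from_stats(self, a, b, variant):
        """Both variants agree with scipy's summary-statistic t-test."""
        res = t_test_summary(SummaryStats(*a), SummaryStats(*b), variant=variant)
        t_ref, p_ref = sps.ttest_ind_from_stats(
            a[1], a[2], a[0], b[1], b[2], b[0], equal_var=(variant == "student")
        )
        assert res.statistic == pytest.approx(float(t_ref), rel=1e-12)
        assert res.p_value == pytest.approx(float(p_ref), rel=1e-9)

    def test_welch_reproduces_reference_cohort_aqueduct_p(self):
        """The unequal-variance form gives p ~= 0.03 on the reference
        aqueduct summary; the pooled form gives ~0.004 — the variants are
        genuinely distinguishable here."""
        a, b = SummaryStats(12, 65, 45), SummaryStats(29, 32, 24)
        w = t_test_summary(a, b, "welch")
        s = t_test_summary(a, b, "student")
        assert w.statistic == pytest.approx(2.40, abs=0.01)
        assert w.df == pytest.approx(13.7, abs=0.1)
        assert round(w.p_value, 2) == 0.03
        assert s.p_value < 0.01

    def test_samples_consistent_with_summary(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 2, 20)
        rs = t_test_samples(x, y)
        rm = t_test_summary(summary_stats(x), summary_stats(y))
        assert rs.statistic == rm.statistic
        assert rs.p_value == rm.p_value

    def test_symmetric_under_group_swap(self):
        a, b = SummaryStats(12, 65, 45), SummaryStats(29, 32, 24)
        r1, r2 = t_test_summary(a, b), t_test_summary(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)


def _brute_force_mw_p(x, y):
    """Independent oracle: exhaustive relabeling of the pooled sample.

    p = 2 * P(U1 <= min(u1, n1 n2 - u1)) over all C(n, n1) group
    assignments, capped at 1 (no ties assumed).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_min = min(u_obs, len(x) * len(y) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        u = sum(1 for xi in g1 for yj in g2 if xi > yj)
        count += u <= u_min
        total += 1
    return min(1.0, 2.0 * count / total)


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.meta["method"] == "exact"

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (2, 5), (4, 4)])
    def test_exact_matches_brute_force_enumeration(self, n1, n2):
        """Exact p equals exhaustive permutation for every rank arrangement."""
        n = n1 + n2
        for subset in itertools.combinations(range(1, n + 1), n1):
            x = np.array(subset, float)
            y = np.array(sorted(set(range(1, n + 1)) - set(subset)), float)
            res = mann_whitney(x, y)
            assert res.p_value == pytest.approx(_brute_force_mw_p(x, y), abs=1e-12)

    def test_large_shift_minimal_p(self):
        x = np.arange(5, dtype=float)
        res = mann_whitney(x, x + 100)
        # most extreme U for n1 = n2 = 5: p = 2 / C(10,5)
        assert res.p_value == pytest.approx(2 / math.comb(10, 5))

    def test_tie_corrected_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(0, 1, 15), 1)
        y = np.round(rng.normal(0.8, 1, 18), 1)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.meta["method"] == "normal_tie_corrected"
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_symmetric_under_group_swap(self):
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0, 11.0]
        assert mann_whitney(x, y).p_value == pytest.approx(mann_whitney(y, x).p_value)


class TestCompareCohort:
    def test_structure_and_test_routing(self):
        table = generate_cohort(CohortSpec(seed=11))
        results = compare_cohort(table)
        names = [r.name for r in results]
        assert names[:5] == ["sv_aqu", "sv_ppc", "sv_fm", "sv_nevrax", "sv_c2c3"]
        assert set(names[5:]) == {"evans_index", "aqueduct_area_mm2"}
        # morphometrics always use the rank test
        for r in results[5:]:
            assert r.test == "mann_whitney"
        for r in results:
            assert 0.0 <= r.p_value <= 1.0

    def test_single_patient_group_rejected(self):
        table = generate_cohort(CohortSpec(seed=0))
        broken = pd.concat(
            [table[table["group"] == "relieved"].iloc[:1], table[table["group"] == "not_relieved"]]
        )
        with pytest.raises(ValueError):
            compare_cohort(broken)

    def test_power_ordering_across_replicates(self):
        """Sites with true group differences (aqu, c2c3) flag significance
        more often than the overlapping sites (ppc, fm, nevrax)."""
        flags = {name: 0 for name in ("sv_aqu", "sv_ppc", "sv_fm", "sv_nevrax", "sv_c2c3")}
        n_rep = 150
        for i in range(n_rep):
            table = generate_cohort(CohortSpec(seed=10_000 + i, with_morphometrics=False, with_outcomes=False))
            for r in compare_cohort(table):
                flags[r.name] += r.significant
        weakest_true_effect = min(flags["sv_aqu"], flags["sv_c2c3"])
        strongest_null_site = max(flags["sv_ppc"], flags["sv_fm"], flags["sv_nevrax"])
        assert weakest_true_effect > strongest_null_site

    def test_holm_adjustment_monotone(self):
        table = generate_cohort(CohortSpec(seed=11))
        results = compare_cohort(table, holm=True)
        for r in results:
            assert r.meta["p_holm"] >= r.p_value


class TestThresholdExclusivity:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_constructed_exclusive_table(self):
        table = self._table(
            [
                {"group": "relieved", "sv_aqu": 110.0, "sv_c2c3": 250.0},
                {"group": "not_relieved", "sv_aqu": 15.0, "sv_c2c3": 850.0},
            ]
        )
        report = threshold_exclusivity(table)
        assert len(report) == 4
        assert all(entry["exclusive"] for entry in report)

    def test_violation_flagged(self):
        table = self._table(
            [
                {"group": "relieved", "sv_aqu": 50.0, "sv_c2c3": 500.0},
                {"group": "not_relieved", "sv_aqu": 120.0, "sv_c2c3": 500.0},
            ]
        )
        report = threshold_exclusivity(table)
        high_aqu = next(e for e in report if e["rule"] == "sv_aqu > 100")
        assert not high_aqu["exclusive"]
        assert high_aqu["n_other_group"] == 1

    def test_empty_rule_set(self):
        table = self._table([{"group": "relieved", "sv_aqu": 1.0}])
        assert threshold_exclusivity(table, ()) == []

    def test_custom_rule(self):
        table = self._table(
            [
                {"group": "relieved", "sv_fm": 900.0},
                {"group": "not_relieved", "sv_fm": 100.0},
            ]
        )
        rule = ThresholdRule("sv_fm", ">", 800.0, "relieved")
        report = threshold_exclusivity(table, (rule,))
        assert report[0]["exclusive"]
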