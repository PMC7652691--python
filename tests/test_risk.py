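"""Pairwise OR machinery: filters, CIs, FDR, directionality, replication."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corisk.errors import ComputationError, DataValidationError
from corisk.risk import (
    OrResult,
    PairRiskResult,
    TwoByTwo,
    bh_adjust,
    cohort_summary,
    filter_low_prevalence,
    filter_zero_comorbidity_patients,
    odds_ratio_ci,
    pairwise_directionality_test,
    pairwise_overall_test,
    replicate_pairs,
)
from conftest import make_cohort


class TestOddsRatioCI:
    def test_cross_product_point_estimate(self):
        assert odds_ratio_ci(TwoByTwo(10, 5, 5, 10)).or_point == pytest.approx(4.0)

    def test_woolf_interval(self):
        # ln 4 +/- 1.96 * sqrt(0.6), computed by hand
        r = odds_ratio_ci(TwoByTwo(10, 5, 5, 10))
        assert r.ci_low == pytest.approx(0.8764, abs=2e-3)
        assert r.ci_high == pytest.approx(18.256, abs=2e-2)

    def test_haldane_zero_cell_rule(self):
        r = odds_ratio_ci(TwoByTwo(5, 0, 5, 10))
        assert r.or_point == pytest.approx((5.5 * 10.5) / (0.5 * 5.5))

    def test_fisher_p_matches_scipy_on_uncorrected_counts(self):
        from scipy.stats import fisher_exact

        r = odds_ratio_ci(TwoByTwo(5, 0, 5, 10))
        assert r.p_raw == pytest.approx(
            fisher_exact([[5, 0], [5, 10]])[1])

    @pytest.mark.parametrize("table", [(0, 0, 5, 5), (5, 5, 0, 0),
                                       (0, 5, 0, 5), (5, 0, 5, 0)])
    def test_degenerate_margins_raise(self, table):
        with pytest.raises(ComputationError, match="degenerate"):
            odds_ratio_ci(TwoByTwo(*table))

    @given(st.tuples(*(st.integers(0, 30),) * 4))
    @settings(max_examples=100, deadline=None)
    def test_transpose_symmetry(self, cells):
        """OR is invariant under simultaneous row and column swap."""
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        r1 = odds_ratio_ci(TwoByTwo(a, b, c, d))
        r2 = odds_ratio_ci(TwoByTwo(d, c, b, a))
        assert r1.or_point == pytest.approx(r2.or_point)
        assert r1.ci_low == pytest.approx(r2.ci_low)
        assert r1.p_raw == pytest.approx(r2.p_raw)


def _bh_brute_force(p):
    """Step-up definition: adj_i = min_{rank>=rank_i} min(1, m*p/rank)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.3], [0.3]),
        ([0.5, 1.0], [1.0, 1.0]),
    ])
    def test_known_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_step_up(self, p):
        assert bh_adjust(p) == pytest.approx(_bh_brute_force(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_dominates_raw_and_caps_at_one(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)


class TestFilters:
    def test_zero_comorbidity_removed(self):
        cohort = make_cohort([[0, 0], [1, 1], [1, 0]], [1, 1, 0])
        out = filter_zero_comorbidity_patients(cohort)
        assert list(out.patient_ids) == ["p1", "p2"]

    def test_all_zero_gives_empty(self):
        cohort = make_cohort([[0, 0], [0, 0]], [1, 0])
        assert filter_zero_comorbidity_patients(cohort).n_patients == 0

    def test_no_zero_rows_identity(self, toy_cohort):
        kept = filter_zero_comorbidity_patients(toy_cohort)
        assert kept.n_patients == 5  # p3 has no comorbidities

    def test_low_prevalence_column_removed(self):
        rng = np.random.default_rng(0)
        X = np.ones((1000, 2), dtype=int)
        X[:, 1] = 0
        X[rng.choice(1000, 5, replace=False), 1] = 1  # 0.5% prevalence
        cohort = make_cohort(X, rng.integers(0, 2, 1000))
        out, removed = filter_low_prevalence(cohort, 0.01)
        assert removed == ["C1"]
        assert out.comorbidity_names == ["C0"]

    def test_all_above_threshold_identity(self, toy_cohort):
        out, removed = filter_low_prevalence(toy_cohort, 0.01)
        assert removed == []
        assert out.comorbidity_names == toy_cohort.comorbidity_names

    def test_patient_emptied_by_column_drop_is_removed(self):
        # p2's only comorbidity is the rare one: dropping it drops p2 too
        X = np.zeros((200, 2), dtype=int)
        X[:199, 0] = 1
        X[199, 1] = 1
        cohort = make_cohort(X, [1, 0] * 100)
        out, removed = filter_low_prevalence(cohort, 0.01)
        assert removed == ["C1"]
        expected = (X[:, [0]].sum(axis=1) > 0).sum()
        assert out.n_patients == expected == 199

    def test_combined_mode_stops_at_union_threshold(self):
        X = np.zeros((1000, 3), dtype=int)
        X[:, 0] = 1          # common
        X[:4, 1] = 1         # 0.4%
        X[4:12, 2] = 1       # 0.8%, union with C1 = 1.2% >= 1%
        cohort = make_cohort(X, [1, 0] * 500)
        _, removed = filter_low_prevalence(cohort, 0.01, mode="combined")
        assert removed == ["C1"]

    def test_bad_threshold(self, toy_cohort):
        with pytest.raises(DataValidationError):
            filter_low_prevalence(toy_cohort, 1.5)


def _cohort_from_2x2(a, b, c, d):
    """Cohort with two comorbidities whose overall 2x2 equals (a,b,c,d);
    unexposed patients carry only comorbidity A."""
    rows, outcome = [], []
    rows += [[1, 1]] * (a + b)
    outcome += [1] * a + [0] * b
    rows += [[1, 0]] * (c + d)
    outcome += [1] * c + [0] * d
    return make_cohort(rows, outcome, ["A", "B"])


class TestPairwiseOverall:
    def test_toy_cross_product(self):
        cohort = _cohort_from_2x2(20, 5, 80, 95)
        res = pairwise_overall_test(cohort)
        assert len(res) == 1
        assert res[0].overall.or_point == pytest.approx(4.75)

    def test_enumeration_count(self):
        rng = np.random.default_rng(1)
        for k in (2, 5, 8):
            cohort = make_cohort(
                rng.integers(0, 2, (60, k)), [1, 0] * 30)
            assert len(pairwise_overall_test(cohort)) == k * (k - 1) // 2

    def test_relabeling_permutes_results(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, (200, 4))
        outcome = rng.integers(0, 2, 200)
        a = pairwise_overall_test(make_cohort(X, outcome))
        perm = [2, 0, 3, 1]
        b = pairwise_overall_test(
            make_cohort(X[:, perm], outcome,
                        names=[f"C{j}" for j in perm]))
        key = lambda r: (tuple(sorted((r.comorbidity_a, r.comorbidity_b))),
                         round(r.overall.or_point, 9) if r.overall else None)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_requires_both_outcome_classes(self):
        cohort = make_cohort([[1, 0], [0, 1]], [1, 1])
        with pytest.raises(DataValidationError):
            pairwise_overall_test(cohort)


class TestDirectionality:
    def _directional_cohort(self):
        """A&B enriches cases against A-only but not against B-only."""
        rows, outcome = [], []
        rows += [[1, 1, 0]] * 60
        outcome += [1] * 40 + [0] * 20      # A&B: 2:1 cases
        rows += [[1, 0, 0]] * 60
        outcome += [1] * 20 + [0] * 40      # A-only: 1:2
        rows += [[0, 1, 0]] * 60
        outcome += [1] * 40 + [0] * 20      # B-only: 2:1 (same as A&B)
        rows += [[0, 0, 1]] * 120
        outcome += [1] * 20 + [0] * 100
        return make_cohort(rows, outcome, ["A", "B", "D"])

    def test_direction_pattern_a_only(self):
        cohort = self._directional_cohort()
        res = pairwise_overall_test(cohort)
        target = [r for r in res if r.key == frozenset({"A", "B"})]
        assert target[0].significant_overall
        pairwise_directionality_test(cohort, [p for p in res
                                              if p.significant_overall])
        assert target[0].direction_pattern == "a_only"
        assert target[0].ab_vs_a.or_point > 1
        assert target[0].ab_vs_b.or_point == pytest.approx(1.0)

    def test_identical_strata_give_unit_or(self):
        rows = [[1, 1]] * 40 + [[1, 0]] * 40
        outcome = ([1] * 20 + [0] * 20) * 2
        cohort = make_cohort(rows, outcome, ["A", "B"])
        pr = PairRiskResult("A", "B", OrResult(1, 1, 1, 1),
                            significant_overall=True)
        pairwise_directionality_test(cohort, [pr])
        assert pr.ab_vs_a.or_point == pytest.approx(1.0)
        assert pr.direction_pattern == "neither"

    def test_both_pattern_flag_logic(self):
        rows, outcome = [], []
        rows += [[1, 1]] * 90
        outcome += [1] * 80 + [0] * 10
        rows += [[1, 0]] * 90
        outcome += [1] * 30 + [0] * 60
        rows += [[0, 1]] * 90
        outcome += [1] * 30 + [0] * 60
        cohort = make_cohort(rows, outcome, ["A", "B"])
        pr = PairRiskResult("A", "B", OrResult(1, 1, 1, 1),
                            significant_overall=True)
        pairwise_directionality_test(cohort, [pr])
        assert pr.direction_pattern == "both"


def _pair(a, b, sig, pattern):
    return PairRiskResult(a, b, OrResult(2.0, 1.5, 3.0, 0.001, 0.01),
                          significant_overall=sig, direction_pattern=pattern)


class TestReplication:
    def test_same_pattern_retained(self):
        out = replicate_pairs([_pair("A", "B", True, "a_only")],
                              [_pair("A", "B", True, "a_only")])
        assert len(out.pairs) == 1
        assert out.unique_comorbidities == {"A", "B"}

    def test_pattern_mismatch_dropped(self):
        out = replicate_pairs([_pair("A", "B", True, "a_only")],
                              [_pair("A", "B", True, "b_only")])
        assert out.pairs == []

    def test_training_only_dropped(self):
        out = replicate_pairs([_pair("A", "B", True, "both")],
                              [_pair("A", "B", False, None)])
        assert out.pairs == []

    def test_neither_never_replicates(self):
        out = replicate_pairs([_pair("A", "B", True, "neither")],
                              [_pair("A", "B", True, "neither")])
        assert out.pairs == []

    def test_orientation_aligned_before_comparison(self):
        # same physical direction recorded with swapped member order
        out = replicate_pairs([_pair("A", "B", True, "a_only")],
                              [_pair("B", "A", True, "b_only")])
        assert len(out.pairs) == 1


class TestCohortSummary:
    def test_median_of_row_sums(self):
        cohort = make_cohort([[1, 0, 0], [1, 1, 0], [1, 1, 1]], [1, 0, 1])
        assert cohort_summary(cohort)["median_comorbidities"] == 2

    def test_empty_cohort_flagged(self):
        cohort = make_cohort(np.zeros((0, 2), dtype=int), [])
        s = cohort_summary(cohort)
        assert s["n_patients"] == 0
        assert s["median_comorbidities"] is None

    def test_prevalence_equals_column_means(self, toy_cohort):
        s = cohort_summary(toy_cohort)
        assert s["prevalence"]["A"] == pytest.approx(3 / 6)
        assert s["n_cases"] == 3
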