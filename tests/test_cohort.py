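"""Relative expression, group comparisons, demographics, stratified analyses."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirscreen import (
    chi_square_independence,
    compare_groups,
    default_cohort_config,
    generate_plasma_cohort,
    group_summary,
    kruskal_groups,
    ratio_percent,
    relative_expression,
    spearman_correlation,
    stratified_comparisons,
)
from mirscreen.cohort import mann_whitney_auc
from mirscreen.synthetic import SubjectRecord
from mirscreen.roc import auc


class TestRelativeExpression:
    @pytest.mark.parametrize("ct_t,ct_r,expected", [
        (25.0, 25.0, 1.0),
        (28.0, 25.0, 0.125),
        (22.0, 25.0, 8.0),
    ])
    def test_power_of_two(self, ct_t, ct_r, expected):
        assert relative_expression(ct_t, ct_r) == pytest.approx(expected)

    def test_published_group_mean_implies_delta_ct(self):
        # expression 0.163 corresponds to a dCt of about 2.617 cycles
        assert -math.log2(0.163) == pytest.approx(2.617, abs=5e-4)
        assert relative_expression(25 + 2.617, 25.0) == pytest.approx(0.163, abs=1e-4)

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(None, 25.0)
        with pytest.raises(ValueError):
            relative_expression(float("nan"), 25.0)


class TestGroupSummary:
    def test_constant_sample(self):
        assert group_summary([1.0, 1.0, 1.0]) == (3, 1.0, 0.0, 1.0)

    def test_hand_computed_example(self):
        n, mean, sem, median = group_summary([1.0, 2.0, 3.0, 4.0])
        assert (n, mean, median) == (4, 2.5, 2.5)
        assert sem == pytest.approx(1.2909944 / 2, abs=1e-4)

    def test_single_value_sem_zero_by_convention(self):
        assert group_summary([7.0]) == (1, 7.0, 0.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestRatioPercent:
    @pytest.mark.parametrize("a,b,expected", [
        (0.163, 0.065, 251),   # IPD / HC
        (0.163, 0.047, 347),   # IPD / NDC
        (1.0, 1.0, 100),
        (0.005, 1.0, 1),       # 0.5 rounds half away from zero
    ])
    def test_published_ratios(self, a, b, expected):
        assert ratio_percent(a, b) == expected

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            ratio_percent(1.0, 0.0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_reciprocal_product_near_ten_thousand(self, a, b):
        prod = ratio_percent(a, b) * ratio_percent(b, a)
        # integer rounding perturbs each factor by at most 0.5
        r = 100 * a / b
        bound = 10_000 * (0.5 / r + 0.5 * r / 10_000 + 0.25 / 10_000) + 1
        assert abs(prod - 10_000) <= bound


class TestCompareGroups:
    def test_exact_mann_whitney_small_sample(self):
        cmp_ = compare_groups([1, 2, 3], [4, 5, 6])
        assert cmp_.statistic == 0.0
        assert cmp_.p_two_sided == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        cmp_ = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert cmp_.p_two_sided == 1.0

    def test_welch_t_option(self):
        cmp_ = compare_groups([2.0, 3.0, 4.0], [0.0, 1.0, 2.0], method="student_t")
        assert cmp_.test_name == "student_t"
        assert cmp_.statistic == pytest.approx(2 / math.sqrt(2 / 3), rel=1e-6)

    def test_summary_fields_and_ratio(self):
        cmp_ = compare_groups([2.0, 4.0], [1.0, 1.0, 1.0],
                              label_a="IPD", label_b="HC")
        assert (cmp_.n_a, cmp_.n_b) == (2, 3)
        assert cmp_.mean_a == 3.0 and cmp_.median_b == 1.0
        assert cmp_.ratio_percent == 300

    def test_synthetic_cohort_headline_comparison(self):
        subjects = generate_plasma_cohort(default_cohort_config(seed=11))
        ipd = [s.expression for s in subjects if s.group == "IPD"]
        hc = [s.expression for s in subjects if s.group == "HC"]
        cmp_ = compare_groups(ipd, hc)
        assert cmp_.p_two_sided < 0.001

    def test_exact_and_asymptotic_branches_agree(self):
        """Exhaustive n=6/6 check: |p_exact - p_approx| <= 0.02 on tie-free data."""
        ranks = list(range(1, 13))
        worst = 0.0
        for case_pos in itertools.combinations(range(12), 6):
            a = [float(ranks[i]) for i in case_pos]
            b = [float(ranks[i]) for i in range(12) if i not in case_pos]
            p_exact = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue
            p_approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic",
                                          use_continuity=True).pvalue
            worst = max(worst, abs(p_exact - min(p_approx, 1.0)))
        assert worst <= 0.02

    def test_u_auc_duality(self, rng):
        a = rng.integers(0, 8, size=25).astype(float)  # with ties
        b = rng.integers(0, 8, size=19).astype(float)
        scores = np.concatenate([a, b])
        labels = [True] * 25 + [False] * 19
        assert mann_whitney_auc(a, b) == pytest.approx(auc(scores, labels), abs=1e-12)


class TestChiSquare:
    def test_independent_table(self):
        chi2, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_published_gender_table_not_significant(self):
        table = np.array([[147, 126], [176, 143], [166, 139]], dtype=float)
        chi2, df, p = chi_square_independence(table)
        # independent hand oracle: sum (O-E)^2/E over the table
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows @ cols / table.sum()
        chi2_oracle = float(((table - expected) ** 2 / expected).sum())
        assert chi2 == pytest.approx(chi2_oracle, rel=1e-12)
        assert df == 2
        assert p > 0.05  # no group difference in sex distribution

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[1, 2, 3]])          # 1 x c
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])     # zero marginal


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        rho, p = spearman_correlation([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)


def test_kruskal_identical_groups():
    assert kruskal_groups([1.0, 1.0], [1.0, 1.0, 1.0]) == (0.0, 1.0)


def make_subject(i, group, age, duration=None, hy=None, medication=None,
                 expression=1.0):
    ct_ref = 20.0
    return SubjectRecord(
        subject_id=f"T{i:03d}", group=group, subgroup=None, sex="male",
        age_years=age, duration_years=duration, hy_stage=hy,
        medication=medication, ct_target=ct_ref - math.log2(expression),
        ct_reference=ct_ref, expression=expression)


class TestStratified:
    def test_age_bin_boundaries(self):
        subjects = [make_subject(1, "IPD", 59.9), make_subject(2, "HC", 59.0),
                    make_subject(3, "IPD", 60.0), make_subject(4, "HC", 65.0),
                    make_subject(5, "IPD", 84.0), make_subject(6, "HC", 81.0)]
        strata = {r.stratum for r in stratified_comparisons(subjects, "age_bins")}
        assert strata == {"40-59", "60-69", "80+"}

    def test_duration_bin_twenty_in_twentyone_out(self):
        subjects = [make_subject(1, "IPD", 60, duration=20.0),
                    make_subject(2, "IPD", 60, duration=21.0),
                    make_subject(3, "HC", 60)]
        results = stratified_comparisons(subjects, "duration_bins")
        assert [r.stratum for r in results] == ["7-20"]
        assert results[0].n_excluded == 1

    def test_ipd_only_strata_compare_against_whole_hc(self):
        subjects = [make_subject(1, "IPD", 60, medication="naive", expression=2.0),
                    make_subject(2, "IPD", 62, medication="l_dopa", expression=2.0),
                    make_subject(3, "HC", 61), make_subject(4, "HC", 63)]
        results = stratified_comparisons(subjects, "medication")
        for r in results:
            cmp_ = r.comparisons["IPD_vs_HC"]
            assert cmp_ is not None and cmp_.n_b == 2

    def test_empty_stratum_reported_absent(self):
        subjects = [make_subject(1, "IPD", 45), make_subject(2, "IPD", 46),
                    make_subject(3, "NDC", 47)]
        results = stratified_comparisons(subjects, "age_bins")
        (r,) = results
        assert r.comparisons["IPD_vs_HC"] is None
        assert r.comparisons["IPD_vs_NDC"] is not None

    def test_constant_expression_yields_no_significance(self):
        subjects = [make_subject(i, g, a) for i, (g, a) in enumerate(
            [("IPD", 45), ("IPD", 55), ("HC", 50), ("HC", 52),
             ("IPD", 65), ("HC", 66), ("NDC", 64), ("NDC", 45)])]
        for stratifier in ("age_bins", "sex"):
            for r in stratified_comparisons(subjects, stratifier):
                for cmp_ in r.comparisons.values():
                    if cmp_ is not None:
                        assert cmp_.p_two_sided == 1.0

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError):
            stratified_comparisons([], "shoe_size")
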