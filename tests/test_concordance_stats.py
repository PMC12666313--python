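import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from odrs.concordance_stats import (
    ContingencyTable,
    categorical_test,
    concordance_rate,
    diagnostic_performance,
    empirical_roc,
    group_compare,
    pearson_r,
    required_enrollment,
    wilson_interval,
)
from odrs.errors import DegenerateLabelsError, DomainError, ValidationError


class TestWilson:
    def test_small_cohort_intervals(self):
        assert wilson_interval(14, 18) == pytest.approx((0.55, 0.91), abs=0.005)
        assert wilson_interval(4, 5) == pytest.approx((0.38, 0.96), abs=0.005)
        assert wilson_interval(3, 5) == pytest.approx((0.23, 0.88), abs=0.005)

    def test_zero_successes_pins_lower_bound(self):
        low, high = wilson_interval(0, 5)
        assert low == 0.0 and 0 < high < 1

    @given(st.integers(min_value=0, max_value=50), st.integers(min_value=1, max_value=50))
    @settings(deadline=None, max_examples=100)
    def test_endpoints_bracket_the_proportion(self, k, n):
        k = min(k, n)
        low, high = wilson_interval(k, n)
        assert 0.0 <= low <= k / n <= high <= 1.0

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = [np.diff(wilson_interval(7 * m, 10 * m))[0] for m in (1, 4, 16)]
        assert widths[0] > widths[1] > widths[2]


class TestDiagnosticPerformance:
    def test_predictive_values_from_counts(self):
        perf = diagnostic_performance(ContingencyTable(tp=14, fp=4, fn=1, tn=4))
        assert perf.ppv == pytest.approx(14 / 18)
        assert perf.npv == pytest.approx(4 / 5)
        perf_b = diagnostic_performance(ContingencyTable(tp=14, fp=4, fn=2, tn=3))
        assert perf_b.npv == pytest.approx(0.6)

    def test_perfect_table(self):
        perf = diagnostic_performance(ContingencyTable(tp=5, fp=0, fn=0, tn=5))
        assert perf.ppv == 1.0 and perf.npv == 1.0

    def test_swap_symmetry(self):
        # swapping classes and predictions exchanges PPV and NPV
        t = ContingencyTable(tp=9, fp=3, fn=2, tn=6)
        swapped = ContingencyTable(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp)
        a, b = diagnostic_performance(t), diagnostic_performance(swapped)
        assert a.ppv == pytest.approx(b.npv) and a.npv == pytest.approx(b.ppv)

    def test_empty_margin(self):
        with pytest.raises(DomainError):
            diagnostic_performance(ContingencyTable(tp=5, fp=5, fn=0, tn=0))


def brute_force_auc(scores, labels):
    """Concordance by pair enumeration: lower score should mean label 1."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p < q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        out = empirical_roc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert out["auroc"] == 1.0

    def test_identical_distributions(self):
        out = empirical_roc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert out["auroc"] == 0.5

    def test_three_vs_three_pair_counting(self):
        scores = [0.2, 0.5, 0.7, 0.4, 0.6, 0.9]
        labels = [1, 1, 1, 0, 0, 0]
        out = empirical_roc(scores, labels)
        assert out["auroc"] == pytest.approx(brute_force_auc(scores, labels))

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_on_small_instances(self, data):
        n = data.draw(st.integers(min_value=4, max_value=12))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(min_value=0, max_value=1, allow_nan=False), min_size=n, max_size=n
            )
        )
        out = empirical_roc(scores, labels)
        assert out["auroc"] == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert 0.0 <= out["auroc_ci"][0] <= out["auroc"] <= out["auroc_ci"][1] <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            empirical_roc([0.1, 0.2], [1, 1])

    def test_roc_points_start_at_origin_and_end_at_one(self):
        out = empirical_roc([0.1, 0.4, 0.6, 0.9], [1, 0, 1, 0])
        assert out["fpr"][0] == 0.0 and out["tpr"][0] == 0.0
        assert out["fpr"][-1] == 1.0 and out["tpr"][-1] == 1.0


class TestPearson:
    def test_perfect_lines(self):
        x = [1.0, 2, 3, 4, 5]
        assert pearson_r(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r, p = pearson_r(x, y)
        rx, ry = x - x.mean(), y - y.mean()
        r_hand = float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
        assert r == pytest.approx(r_hand)
        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3))

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_two_groups_use_rank_sum(self):
        out = group_compare([1, 2, 3, 11, 12, 13], ["a"] * 3 + ["b"] * 3)
        assert out["test"] == "mann-whitney"
        assert out["p"] == pytest.approx(0.1, abs=0.001)  # exact MW p for full separation 3v3

    def test_kruskal_wallis_hand_value(self):
        values = [1, 2, 3, 101, 102, 103, 201, 202, 203]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = group_compare(values, groups)
        assert out["test"] == "kruskal-wallis"
        assert out["statistic"] == pytest.approx(7.2)
        assert set(out["posthoc"]) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(0 <= p <= 1 for p in out["posthoc"].values())

    def test_identical_groups_give_zero_statistic(self):
        out = group_compare([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert out["statistic"] == 0.0 and out["p"] == 1.0

    def test_dunn_bonferroni_multiplies_raw_p(self):
        values = np.concatenate(
            [np.arange(10.0), np.arange(10.0) + 3.0, np.arange(10.0) + 30.0]
        )
        groups = np.repeat(["a", "b", "c"], 10)
        out = group_compare(values, groups)
        # extreme pair far more significant than the adjacent pair
        assert out["posthoc"][("a", "c")] < out["posthoc"][("a", "b")]

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            group_compare([1.0, 2.0], ["a", "a"])


class TestCategoricalTest:
    def test_balanced_table_uses_chi_square(self):
        out = categorical_test([[20, 20], [20, 20]])
        assert out["test"] == "chi-square"
        assert out["p"] == pytest.approx(1.0)

    def test_sparse_2x2_uses_fisher(self):
        out = categorical_test([[8, 2], [3, 7]])
        assert out["test"] == "fisher"
        assert out["min_expected"] == pytest.approx(4.5)

    def test_selection_is_pure_function_of_expected_counts(self):
        # scaling the same proportions up past the threshold flips the test
        assert categorical_test([[8, 2], [3, 7]])["test"] == "fisher"
        assert categorical_test([[80, 20], [30, 70]])["test"] == "chi-square"

    def test_sparse_3x2_falls_back_to_chi_square(self):
        out = categorical_test([[8, 2], [3, 7], [5, 5]])
        assert out["test"] == "chi-square"

    def test_zero_row_rejected(self):
        with pytest.raises(DomainError):
            categorical_test([[0, 0], [3, 7]])


def test_concordance_rate_examples():
    a = ["mut"] * 68 + ["wt"] * 4
    b = ["mut"] * 72
    assert round(concordance_rate(a, b)) == 94
    assert concordance_rate([1, 2], [1, 2]) == 100.0
    assert concordance_rate([1, 2], [1, 3]) == 50.0
    with pytest.raises(ValidationError):
        concordance_rate([1], [1, 2])


def test_required_enrollment():
    assert required_enrollment(85, 0.56) == 193
    assert required_enrollment(10, 0.0) == 10
    assert required_enrollment(85, 0.50) == 170
    with pytest.raises(DomainError):
        required_enrollment(85, 1.0)
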