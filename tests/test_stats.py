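import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from puncta import (
    dunnett_t3,
    mann_whitney_test,
    rout_outliers,
    tukey_box_summary,
    welch_t_test,
)
from puncta.errors import StatsError


def exact_mann_whitney_p(a, b):
    """Enumeration oracle: two-tailed exact p over all group assignments."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    u_hi = max(u_obs, na * len(b) - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y)
        total += 1
        if max(u, na * len(gb) - u) >= u_hi:
            count += 1
    return count / total


class TestWelch:
    def test_worked_example(self):
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.224744871, abs=1e-8)
        assert res.df == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.2878641347, abs=1e-8)

    def test_identical_samples_give_p_one(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = welch_t_test([1, 1], [2, 2])
        assert res.p_value == 0.0

    def test_zero_variance_equal_means(self):
        res = welch_t_test([2, 2, 2], [2, 2])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_n_below_two_rejected(self):
        with pytest.raises(StatsError):
            welch_t_test([1], [2, 3])

    def test_agrees_with_scipy_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 12))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 12))
            mine = welch_t_test(a, b)
            oracle = sps.ttest_ind(a, b, equal_var=False)
            assert mine.statistic == pytest.approx(oracle.statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(oracle.pvalue, abs=1e-8)
            assert mine.df == pytest.approx(oracle.df, abs=1e-8)


class TestMannWhitney:
    def test_worked_example_exact(self):
        res = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "mann_whitney_exact"

    def test_identical_groups_p_one(self):
        res = mann_whitney_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "mann_whitney_normal_approx"  # ties force approximation

    def test_single_observation_group_valid(self):
        res = mann_whitney_test([2.5], [1, 2, 3, 4])
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney_test([], [1, 2])

    def test_agrees_with_enumeration_oracle_on_random_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(200):  # exact enumeration is the slow part
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            mine = mann_whitney_test(a, b)
            assert mine.method == "mann_whitney_exact"
            assert mine.p_value == pytest.approx(exact_mann_whitney_p(a, b), abs=1e-8)


class TestDunnettT3:
    def test_two_groups_adjusted_equals_welch(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, 10)
        table = dunnett_t3({"a": a, "b": b}, mc_reps=1000, seed=0)
        (comp,) = table.comparisons
        assert comp["p_adjusted"] == pytest.approx(welch_t_test(a, b).p_value)

    def test_adjusted_p_bounds(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(size=12) for k in "abcd"}
        table = dunnett_t3(groups, mc_reps=50_000, seed=1)
        for comp in table.comparisons:
            assert comp["p_adjusted"] >= comp["p_raw"]
            assert 0.0 <= comp["p_adjusted"] <= 1.0
            # never beats the Sidak bound by more than Monte-Carlo noise
            assert comp["p_adjusted"] <= comp["p_sidak"] + 0.01

    def test_adjusted_p_monotone_in_number_of_comparisons(self):
        rng = np.random.default_rng(4)
        data = {k: rng.normal(size=10) for k in "abcde"}
        p2 = dunnett_t3({k: data[k] for k in "ab"}, mc_reps=20_000, seed=5)
        p5 = dunnett_t3(data, mc_reps=20_000, seed=5)
        pair = lambda t: next(  # noqa: E731
            c for c in t.comparisons if {c["group_a"], c["group_b"]} == {"a", "b"}
        )
        assert pair(p5)["p_adjusted"] >= pair(p2)["p_adjusted"]

    def test_widely_separated_groups_all_significant(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(10, 1, 15),
            "c": rng.normal(20, 1, 15),
        }
        table = dunnett_t3(groups, mc_reps=20_000, seed=2)
        assert all(c["p_adjusted"] < 0.001 for c in table.comparisons)

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(6)
        g = {k: rng.normal(size=8) for k in "abc"}
        t1 = dunnett_t3(g, mc_reps=10_000, seed=3)
        t2 = dunnett_t3(dict(reversed(list(g.items()))), mc_reps=10_000, seed=3)
        p1 = {frozenset((c["group_a"], c["group_b"])): c["t"] for c in t1.comparisons}
        p2 = {frozenset((c["group_a"], c["group_b"])): c["t"] for c in t2.comparisons}
        for k in p1:
            assert abs(p1[k]) == pytest.approx(abs(p2[k]))

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            dunnett_t3({"a": [1.0], "b": [1.0, 2.0]})


class TestRout:
    def test_constant_data_no_outliers(self):
        res = rout_outliers([5, 5, 5, 5], Q=1.0)
        assert res.flagged == []
        assert res.kept == [5, 5, 5, 5]

    def test_gross_contaminant_flagged(self):
        rng = np.random.default_rng(7)
        x = np.append(rng.normal(size=14), 100.0)
        res = rout_outliers(x, Q=1.0)
        assert res.flagged == [100.0]
        assert len(res.kept) == 14

    def test_partition_preserves_multiset(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        res = rout_outliers(x, Q=5.0)
        assert sorted(res.kept + res.flagged) == sorted(x.tolist())

    def test_center_estimate_robust_to_contaminant(self):
        rng = np.random.default_rng(9)
        x = np.append(rng.normal(3.0, 1.0, 30), 1000.0)
        res = rout_outliers(x, Q=1.0)
        assert abs(res.center_estimate - 3.0) < 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            rout_outliers([1.0, 2.0], Q=1.0)
        with pytest.raises(StatsError):
            rout_outliers([1.0, 2.0, 3.0], Q=0.0)


class TestTukeyBox:
    def test_worked_example(self):
        box = tukey_box_summary([1, 2, 3, 4, 100])
        assert box.q1 == 2.0 and box.q3 == 4.0 and box.median == 3.0
        assert box.whisker_high == 4.0  # most extreme point within Q3 + 1.5 IQR = 7
        assert box.outliers == [100.0]

    def test_constant_data_degenerate_box(self):
        box = tukey_box_summary([7.0] * 6)
        assert box.q1 == box.q3 == box.median == 7.0
        assert box.outliers == []

    def test_single_value(self):
        box = tukey_box_summary([3.5])
        assert box.median == 3.5
        assert box.whisker_low == box.whisker_high == 3.5
        assert box.outliers == []


def test_all_p_values_in_unit_interval_on_random_data():
    rng = np.random.default_rng(10)
    for _ in range(50):
        a = rng.normal(size=rng.integers(2, 20))
        b = rng.normal(size=rng.integers(2, 20))
        for res in (welch_t_test(a, b), mann_whitney_test(a, b)):
            assert 0.0 <= res.p_value <= 1.0


def test_group_order_invariance_of_two_sample_tests():
    rng = np.random.default_rng(11)
    a, b = rng.normal(size=9), rng.normal(0.5, 2.0, 13)
    w_ab, w_ba = welch_t_test(a, b), welch_t_test(b, a)
    assert w_ab.p_value == pytest.approx(w_ba.p_value)
    assert w_ab.statistic == pytest.approx(-w_ba.statistic)
    m_ab, m_ba = mann_whitney_test(a, b), mann_whitney_test(b, a)
    assert m_ab.p_value == pytest.approx(m_ba.p_value)
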