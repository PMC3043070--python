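import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirmint.io import ExpressionMatrix
from mirmint.tnom import (
    LabeledVector,
    bh_fdr,
    differential_expression_table,
    log2_fold_change,
    t_test_pvalue,
    tnom_exact_pvalue,
    tnom_null_distribution,
    tnom_statistic,
)


def brute_force_tnom(values, labels):
    """Independent statistic oracle: try every threshold midpoint and
    both orientations directly on the data."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    cuts = np.concatenate(
        [[values.min() - 1], np.unique(values)[:-1] + np.diff(np.unique(values)) / 2,
         [values.max() + 1]]
    )
    best = len(labels)
    for c in cuts:
        low = values <= c
        err_ones_low = np.sum(labels[low] == 0) + np.sum(labels[~low] == 1)
        err_zeros_low = np.sum(labels[low] == 1) + np.sum(labels[~low] == 0)
        best = min(best, err_ones_low, err_zeros_low)
    return int(best)


def enum_cdf(n1, n0):
    """Null CDF by exhaustive enumeration of all C(N, n1) arrangements."""
    N = n1 + n0
    ks = []
    for pos in itertools.combinations(range(N), n1):
        lab = np.zeros(N, int)
        lab[list(pos)] = 1
        ks.append(tnom_statistic(LabeledVector(np.arange(N, dtype=float), lab)))
    ks = np.asarray(ks)
    return {k: float((ks <= k).mean()) for k in range(min(n1, n0) + 1)}


class TestStatistic:
    @pytest.mark.parametrize(
        "labels,expected",
        [([1, 1, 0, 0], 0), ([1, 0, 1, 0], 1), ([0, 0, 1, 1], 0),
         ([1, 0, 0, 1], 1), ([1, 1, 1, 1], 0), ([0, 1, 1, 0, 0, 1], 2)],
    )
    def test_small_cases_match_enumerated_cuts(self, labels, expected):
        values = np.arange(len(labels), dtype=float)
        v = LabeledVector(values, labels)
        assert tnom_statistic(v) == expected
        assert tnom_statistic(v) == brute_force_tnom(values, labels)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 14))
    def test_matches_threshold_oracle_on_random_data(self, seed, n):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        v = LabeledVector(values, labels)
        assert tnom_statistic(v) == brute_force_tnom(values, labels)

    def test_constant_vector_admits_no_cut(self):
        v = LabeledVector(np.zeros(10), [1] * 4 + [0] * 6)
        assert tnom_statistic(v) == 4
        assert tnom_exact_pvalue(v) == 1.0


class TestNullDistribution:
    def test_worked_cell_2v2(self):
        d = tnom_null_distribution(2, 2)
        assert d[0] == pytest.approx(1 / 3, abs=1e-15)
        assert d[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n0", [(3, 5), (1, 9), (6, 6), (2, 10)])
    def test_prefix_suffix_closed_form_at_k0(self, n1, n0):
        # only the two fully separated arrangements achieve k = 0
        assert tnom_null_distribution(n1, n0)[0] == pytest.approx(
            2 / comb(n1 + n0, n1), rel=1e-12
        )

    @pytest.mark.parametrize("n1,n0", [(2, 3), (4, 4), (3, 6), (5, 5)])
    def test_matches_enumeration(self, n1, n0):
        expected = enum_cdf(n1, n0)
        got = tnom_null_distribution(n1, n0)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)

    def test_symmetry_in_class_sizes(self):
        assert tnom_null_distribution(4, 7) == tnom_null_distribution(7, 4)

    def test_strictly_increasing_until_one(self):
        d = tnom_null_distribution(10, 14)
        values = [d[k] for k in sorted(d)]
        below = [v for v in values if v < 1]
        assert all(b < a for b, a in zip(below, below[1:] + [1.0]))
        assert values[-1] == pytest.approx(1.0)


class TestExactPvalue:
    def test_separated_labels(self):
        v = LabeledVector([0.0, 1.0, 2.0, 3.0], [1, 1, 0, 0])
        assert tnom_exact_pvalue(v) == pytest.approx(1 / 3, abs=1e-12)

    def test_interleaved_labels(self):
        v = LabeledVector([0.0, 1.0, 2.0, 3.0], [1, 0, 1, 0])
        assert tnom_exact_pvalue(v) == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            tnom_exact_pvalue(LabeledVector([1.0, 2.0], [1, 1]))


class TestTTest:
    def test_identical_distributions_give_p_one(self):
        v = LabeledVector([1.0, 2.0, 1.0, 2.0], [1, 1, 0, 0])
        assert t_test_pvalue(v) == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=12)
        labels = np.array([1] * 5 + [0] * 7)
        a = t_test_pvalue(LabeledVector(vals, labels))
        b = t_test_pvalue(LabeledVector(vals, 1 - labels))
        assert a == pytest.approx(b)

    def test_degenerate_zero_variance(self):
        v = LabeledVector([0.0, 0.0, 1.0, 1.0], [1, 1, 0, 0])
        assert t_test_pvalue(v) == np.finfo(float).tiny


class TestBhFdr:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    def test_monotone_in_sorted_order_and_bounded(self, ps):
        q = bh_fdr(ps)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDifferentialTable:
    def make_matrix(self, seed=0, planted_shift=4.0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(8, 1, (20, 16))
        vals[0, :8] += planted_shift  # planted feature, up in class A
        return ExpressionMatrix(
            [f"f{i:02d}" for i in range(20)],
            [f"s{j}" for j in range(16)],
            vals,
            "log2",
        )

    def test_planted_feature_ranks_first(self):
        m = self.make_matrix()
        table = differential_expression_table(
            m, [f"s{j}" for j in range(8)], [f"s{j}" for j in range(8, 16)]
        )
        assert table.iloc[0]["feature_id"] == "f00"
        assert table.iloc[0]["direction"] == "up"
        assert table.iloc[0]["q"] >= table.iloc[0]["tnom_p"]

    def test_sample_permutation_invariance(self):
        m = self.make_matrix()
        a = [f"s{j}" for j in range(8)]
        b = [f"s{j}" for j in range(8, 16)]
        t1 = differential_expression_table(m, a, b)
        m2 = m.select_samples(list(reversed(m.sample_ids)))
        t2 = differential_expression_table(m2, a, b)
        for col in ("feature_id", "k", "tnom_p", "t_p", "log2_fc"):
            np.testing.assert_array_equal(t1[col].to_numpy(), t2[col].to_numpy())

    def test_constant_feature_gets_p_one(self):
        m = self.make_matrix()
        m.values[5, :] = 3.0
        table = differential_expression_table(
            m, [f"s{j}" for j in range(8)], [f"s{j}" for j in range(8, 16)]
        )
        row = table[table.feature_id == "f05"].iloc[0]
        assert row["k"] == 8 and row["tnom_p"] == pytest.approx(1.0)

    def test_overlapping_classes_rejected(self):
        m = self.make_matrix()
        with pytest.raises(ValueError):
            differential_expression_table(m, ["s0", "s1"], ["s1", "s2"])

    def test_direction_consistent_with_fold_change(self):
        m = self.make_matrix()
        table = differential_expression_table(
            m, [f"s{j}" for j in range(8)], [f"s{j}" for j in range(8, 16)]
        )
        up = table["direction"] == "up"
        assert np.all(table.loc[up, "log2_fc"] >= 0)
        assert np.all(table.loc[~up, "log2_fc"] < 0)
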