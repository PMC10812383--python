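"""Nonparametric comparisons against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

import polestrat as ps
from polestrat.stats import ComparisonRefused, significance_stars


def exact_mwu_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(
            sum(1 for x in xs for y in ys if x > y)
            + 0.5 * sum(1 for x in xs for y in ys if x == y)
        )
    lo = min(u_obs, n_a * len(b) - u_obs)
    hi = n_a * len(b) - lo
    p = sum(1 for u in us if u <= lo or u >= hi) / len(us)
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = ps.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_exact_p(self):
        res = ps.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of 20 splits as extreme
        assert res.u_statistic == 0

    @pytest.mark.parametrize("n_a", [1, 2])
    def test_tiny_samples_refused(self, n_a):
        with pytest.raises(ComparisonRefused, match="refused"):
            ps.mann_whitney([1.0] * n_a, [1, 2, 3, 4])

    def test_exact_agrees_with_enumeration_up_to_n10(self):
        """Implementation matches full permutation enumeration (no ties)."""
        rng = np.random.default_rng(7)
        for n_a in range(3, 8):
            for n_b in range(3, 11 - n_a):
                for _ in range(3):
                    pool = rng.permutation(100)[: n_a + n_b].astype(float)
                    a, b = list(pool[:n_a]), list(pool[n_a:])
                    res = ps.mann_whitney(a, b)
                    u_oracle, p_oracle = exact_mwu_oracle(a, b)
                    assert res.method == "exact"
                    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
                    assert res.u_statistic == pytest.approx(u_oracle)

    def test_u_statistics_complementary(self):
        rng = np.random.default_rng(3)
        a = list(rng.normal(size=9))
        b = list(rng.normal(1, size=7))
        ua = ps.mann_whitney(a, b).u_statistic
        ub = ps.mann_whitney(b, a).u_statistic
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_ties_fall_back_to_normal_approximation(self):
        res = ps.mann_whitney([1, 2, 2, 3], [2, 3, 4, 5])
        assert res.method == "normal_approx"
        assert 0 <= res.p_value <= 1


class TestBhFdr:
    def test_single_p_identity(self):
        assert ps.bh_fdr([0.05]) == [pytest.approx(0.05)]

    def test_step_up_hand_example(self):
        # min over k >= i of m * p(k) / k: all collapse to 0.04
        assert ps.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_order_preserved_and_monotone_on_sorted_input(self):
        p = [0.001, 0.01, 0.02, 0.2, 0.9]
        adj = ps.bh_fdr(p)
        assert adj == sorted(adj)
        shuffled = [p[i] for i in (3, 0, 4, 1, 2)]
        adj_shuffled = ps.bh_fdr(shuffled)
        assert adj_shuffled[1] == pytest.approx(adj[0])

    def test_bounded_and_dominates_raw(self):
        rng = np.random.default_rng(5)
        p = list(rng.uniform(size=20))
        once = ps.bh_fdr(p)
        assert all(0 <= q <= 1 for q in once)
        assert all(q >= raw for q, raw in zip(once, p))
        # step-up oracle: q(i) = min over k >= i of m * p(k) / k
        order = np.argsort(p)
        m = len(p)
        sorted_p = np.array(p)[order]
        oracle_sorted = np.minimum.accumulate(
            (m * sorted_p / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert once == pytest.approx(list(oracle))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.bh_fdr([0.5, 1.2])


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2, 3, 5, 8]
        assert ps.spearman(x, x)[0] == pytest.approx(1.0)
        assert ps.spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d the rank differences
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))  # ranks = values here
        expected = 1 - 6 * d2 / (5 * 24)
        rho, p = ps.spearman(x, y)
        assert rho == pytest.approx(expected)  # = 0.8
        assert 0 <= p <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ps.spearman([1, 2, 3], [1, 2])


class TestMedianRange:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([114, 264, 265, 414], (264.5, 114, 414)),
            ([7], (7, 7, 7)),
            ([3, 9], (6.0, 3, 9)),
        ],
    )
    def test_midpoint_convention(self, values, expected):
        assert ps.median_range(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.median_range([])


def test_significance_star_mapping():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == "NS"
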