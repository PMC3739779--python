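import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locotrace.errors import ValidationError
from locotrace.stats import (arcsine_sqrt, bonferroni_dunn, one_way_anova,
                             pearson_test, significance_stars, t_test_equal_var,
                             two_way_anova)


def hand_pooled_t(x, y):
    """Closed-form pooled-variance t statistic, written out independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestTTest:
    def test_identical_samples(self):
        r = t_test_equal_var([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.stars == "NS"

    def test_matches_hand_computed_pooled_formula(self):
        x, y = (1.0, 2.0, 3.0), (1.0, 2.0, 3.0, 4.0)
        r = t_test_equal_var(x, y)
        assert r.statistic == pytest.approx(hand_pooled_t(x, y), rel=1e-12)
        assert r.df == 5

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        a, b = t_test_equal_var(x, y), t_test_equal_var(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_different_means_flagged(self):
        r = t_test_equal_var([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(r.statistic) and r.p_value == 0.0 and r.flagged

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            t_test_equal_var([1.0], [1.0, 2.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 20))
            y = rng.normal(0.3, 1, rng.integers(3, 20))
            F = one_way_anova({"x": x, "y": y}).loc["between_groups", "F"]
            t = t_test_equal_var(x, y).statistic
            assert abs(F - t ** 2) <= 1e-9 * max(abs(F), 1.0)

    def test_total_ss_decomposition_matches_brute_force(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(i, 1.0, 7) for i in range(4)}
        table = one_way_anova(groups)
        alldata = np.concatenate(list(groups.values()))
        total_ss = np.sum((alldata - alldata.mean()) ** 2)
        assert table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-12)

    def test_two_way_additive_design_has_zero_interaction(self):
        a_eff = {"s1": 0.0, "s2": 3.0}
        b_eff = {"t1": 0.0, "t2": -1.0, "t3": 2.0}
        values, fa, fb = [], [], []
        for a, av in a_eff.items():
            for b, bv in b_eff.items():
                for _ in range(3):
                    values.append(10 + av + bv)
                    fa.append(a)
                    fb.append(b)
        table = two_way_anova(values, fa, fb)
        assert table.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(table.loc["factor_a", "F"])  # zero residual: flagged

    def test_two_way_ss_matches_projection_oracle(self):
        """Balanced-design SS from cell/marginal means, computed directly."""
        rng = np.random.default_rng(9)
        levels_a, levels_b, reps = 3, 4, 5
        values, fa, fb = [], [], []
        for i in range(levels_a):
            for j in range(levels_b):
                for _ in range(reps):
                    values.append(rng.normal(i * 0.7 + j * 0.3 + (i == j), 1.0))
                    fa.append(f"a{i}")
                    fb.append(f"b{j}")
        v = np.asarray(values).reshape(levels_a, levels_b, reps)
        grand = v.mean()
        ss_a = levels_b * reps * np.sum((v.mean(axis=(1, 2)) - grand) ** 2)
        ss_b = levels_a * reps * np.sum((v.mean(axis=(0, 2)) - grand) ** 2)
        cell = v.mean(axis=2)
        ss_int = reps * np.sum(
            (cell - v.mean(axis=(1, 2))[:, None] - v.mean(axis=(0, 2))[None, :]
             + grand) ** 2)
        ss_res = np.sum((v - cell[:, :, None]) ** 2)
        table = two_way_anova(values, fa, fb)
        assert table.loc["factor_a", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert table.loc["factor_b", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert table.loc["interaction", "sum_sq"] == pytest.approx(ss_int, rel=1e-9)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_res, rel=1e-9)

    def test_empty_cell_named_in_error(self):
        with pytest.raises(ValidationError, match="a2.*b1|b1.*a2"):
            two_way_anova([1.0, 2.0, 3.0], ["a1", "a1", "a2"], ["b1", "b2", "b2"])


class TestBonferroniDunn:
    def test_six_groups_adjusted_alpha(self):
        """Six strains give 15 pairs: 0.05 / 15 = 0.00333..."""
        rng = np.random.default_rng(12)
        groups = {s: rng.normal(0, 1, 8) for s in "abcdef"}
        cm = bonferroni_dunn(groups, alpha=0.05)
        assert cm.adjusted_alpha == pytest.approx(0.05 / 15)
        assert round(cm.adjusted_alpha, 4) == 0.0033
        assert cm.adjusted_alpha * 15 == 0.05

    def test_two_groups_reduces_to_equal_variance_t(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
        cm = bonferroni_dunn({"x": x, "y": y})
        t_bd = cm.get("x", "y").statistic
        t_plain = t_test_equal_var(x, y).statistic
        assert t_bd == pytest.approx(t_plain, rel=1e-12)
        F = one_way_anova({"x": x, "y": y}).loc["between_groups", "F"]
        assert F == pytest.approx(t_bd ** 2, rel=1e-9)

    def test_equal_means_nothing_significant(self):
        groups = {s: np.array([1.0, 2.0, 3.0]) for s in "abcd"}
        cm = bonferroni_dunn(groups)
        assert not any(cm.significant(a, b)
                       for a in "abcd" for b in "abcd" if a < b)

    def test_star_matrix_is_symmetric(self):
        rng = np.random.default_rng(14)
        cm = bonferroni_dunn({s: rng.normal(i, 1, 6)
                              for i, s in enumerate("abc")})
        frame = cm.star_frame()
        assert (frame.values == frame.values.T).all()


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        r = pearson_test(x, 2 * x + 1)
        assert r.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_test(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        res = pearson_test(x, y)
        assert res.statistic == pytest.approx(r_hand, rel=1e-12)
        assert res.df == 3

    def test_affine_invariance(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        r0 = pearson_test(x, y).statistic
        r1 = pearson_test(3.0 * x + 7.0, 0.5 * y - 2.0).statistic
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestArcsine:
    def test_endpoints_and_midpoint(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(np.pi / 2)
        assert arcsine_sqrt(0.5) == pytest.approx(np.pi / 4)

    def test_complementary_identity(self):
        for p in (0.25, 0.1, 0.6789):
            assert arcsine_sqrt(p) + arcsine_sqrt(1 - p) == pytest.approx(np.pi / 2)

    def test_monotone_on_grid(self):
        grid = np.linspace(0, 1, 101)
        vals = arcsine_sqrt(grid)
        assert np.all(np.diff(vals) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            arcsine_sqrt(1.2)


class TestStars:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_stars_consistent_with_p(self, p):
        s = significance_stars(p)
        if p < 0.001:
            assert s == "***"
        elif p < 0.01:
            assert s == "**"
        elif p < 0.05:
            assert s == "*"
        else:
            assert s == "NS"
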