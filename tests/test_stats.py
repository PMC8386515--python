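"""Statistical battery: worked examples, enumeration oracles, conventions."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from antlook.stats import (
    StatsError,
    anova_2x2_between,
    exact_binomial_two_tailed,
    fisher_exact_two_tailed,
    mixed_anova_duration,
    one_sample_t,
    welch_t,
)

from conftest import binomial_p_oracle, fisher_p_oracle


class TestExactBinomial:
    def test_both_outcomes_equally_probable(self):
        assert exact_binomial_two_tailed(0, 1, 0.5).p == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # outcomes with pmf <= pmf(2): {0,1,2,8,9,10} -> 112/1024
        assert exact_binomial_two_tailed(2, 10, 0.5).p == pytest.approx(112 / 1024)

    def test_symmetry_at_half(self):
        for k, n in ((3, 11), (0, 7), (5, 12)):
            assert exact_binomial_two_tailed(k, n, 0.5).p == pytest.approx(
                exact_binomial_two_tailed(n - k, n, 0.5).p
            )

    def test_estimate_and_domain_errors(self):
        res = exact_binomial_two_tailed(22, 49, 0.5)
        assert res.estimate == pytest.approx(22 / 49)
        with pytest.raises(StatsError):
            exact_binomial_two_tailed(0, 0, 0.5)
        with pytest.raises(StatsError):
            exact_binomial_two_tailed(1, 2, 1.0)

    @pytest.mark.parametrize("p0", [Fraction(1, 2), Fraction(3, 10)])
    def test_full_enumeration_oracle_all_small_n(self, p0):
        for n in range(1, 13):
            for k in range(n + 1):
                expected = float(binomial_p_oracle(k, n, p0))
                got = exact_binomial_two_tailed(k, n, float(p0)).p
                assert got == pytest.approx(expected, abs=1e-9), (k, n, p0)


class TestFisherExact:
    def test_two_equiprobable_tables(self):
        assert fisher_exact_two_tailed([[1, 0], [0, 1]]).p == pytest.approx(1.0)

    def test_hand_enumerated_diagonal(self):
        # margins (3,3)/(3,3): 4 tables, the two extremes have pmf 1/20 each
        assert fisher_exact_two_tailed([[3, 0], [0, 3]]).p == pytest.approx(0.1)

    def test_transpose_and_row_swap_invariance(self):
        t = [[5, 2], [1, 4]]
        base = fisher_exact_two_tailed(t).p
        assert fisher_exact_two_tailed([[5, 1], [2, 4]]).p == pytest.approx(base)
        assert fisher_exact_two_tailed([[1, 4], [5, 2]]).p == pytest.approx(base)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = fisher_exact_two_tailed([[0, 0], [3, 2]])
        assert res.p == 1.0

    def test_full_enumeration_oracle_all_small_tables(self):
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        expected = float(fisher_p_oracle(t))
                        got = fisher_exact_two_tailed(t).p
                        assert got == pytest.approx(expected, abs=1e-9), t


class TestTTests:
    def test_one_sample_hand_computation(self):
        # mean 2, sd 1, se 1/sqrt(3) -> t = 2*sqrt(3), df = 2
        res = one_sample_t([1, 2, 3], 0.0)
        assert res.statistic == pytest.approx(2 * math.sqrt(3))
        assert res.df == 2

    def test_symmetric_values_give_t_zero(self):
        res = one_sample_t([0.4, 0.6, 0.3, 0.7], 0.5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_nan_dropped_before_df(self):
        vals = [0.1, 0.9, 0.4, float("nan")]
        assert one_sample_t(vals, 0.5).df == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            one_sample_t([0.5, 0.5, 0.5], 0.5)

    def test_welch_hand_example(self):
        # s2a = 0.5 (n=2), s2b = 1 (n=3): Satterthwaite df ~ 2.8824
        res = welch_t([0, 1], [0, 1, 2])
        se2 = 0.5 / 2 + 1 / 3
        df = se2**2 / ((0.25) ** 2 / 1 + (1 / 3) ** 2 / 2)
        assert res.df == pytest.approx(df)
        assert res.statistic == pytest.approx((0.5 - 1.0) / math.sqrt(se2))

    def test_welch_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_equal_variance_equal_n_limit(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        b = a + 5  # identical sample variance
        assert welch_t(a, b).df == pytest.approx(2 * 12 - 2)

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=15),
        st.lists(st.floats(-5, 5), min_size=3, max_size=15),
    )
    @settings(max_examples=60, deadline=None)
    def test_welch_df_bounds(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
            return
        df = welch_t(a, b).df
        assert min(len(a), len(b)) - 1 <= df + 1e-9
        assert df <= len(a) + len(b) - 2 + 1e-9


def _balanced_anova_oracle(y, f1, f2):
    """Closed-form balanced two-way ANOVA (equal cell sizes)."""
    df = pd.DataFrame({"y": y, "a": f1, "b": f2})
    grand = df["y"].mean()
    n_cell = len(df) // 4
    cell = df.groupby(["a", "b"])["y"].mean()
    ma = df.groupby("a")["y"].mean()
    mb = df.groupby("b")["y"].mean()
    ss_a = 2 * n_cell * sum((m - grand) ** 2 for m in ma)
    ss_b = 2 * n_cell * sum((m - grand) ** 2 for m in mb)
    ss_ab = n_cell * sum(
        (cell[a, b] - ma[a] - mb[b] + grand) ** 2
        for a in ma.index
        for b in mb.index
    )
    ss_e = sum(
        (row.y - cell[row.a, row.b]) ** 2 for row in df.itertuples()
    )
    dfe = len(df) - 4
    return {
        "f1": ss_a / (ss_e / dfe),
        "f2": ss_b / (ss_e / dfe),
        "interaction": ss_ab / (ss_e / dfe),
    }


def _type3_lstsq_oracle(y, f1, f2):
    """Type-III F by explicit model comparison with sum-coded design."""
    y = np.asarray(y, dtype=float)
    a = np.where(np.asarray(f1) == sorted(set(f1))[0], 1.0, -1.0)
    b = np.where(np.asarray(f2) == sorted(set(f2))[0], 1.0, -1.0)
    X = np.column_stack([np.ones_like(y), a, b, a * b])

    def sse(cols):
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        r = y - X[:, cols] @ beta
        return float(r @ r)

    full = sse([0, 1, 2, 3])
    dfe = len(y) - 4
    out = {}
    for name, drop in (("f1", 1), ("f2", 2), ("interaction", 3)):
        reduced = sse([c for c in range(4) if c != drop])
        out[name] = ((reduced - full) / 1) / (full / dfe)
    return out


class TestBetweenAnova:
    def test_balanced_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        n = 10
        f1 = ["FB1"] * 2 * n + ["FB2"] * 2 * n
        f2 = (["inc"] * n + ["exc"] * n) * 2
        effect = {("FB1", "inc"): 0.6, ("FB1", "exc"): 0.45,
                  ("FB2", "inc"): 0.5, ("FB2", "exc"): 0.35}
        y = [effect[a, b] + rng.normal(0, 0.08) for a, b in zip(f1, f2)]
        table = anova_2x2_between(y, f1, f2, names=("cond", "incl"))
        oracle = _balanced_anova_oracle(y, f1, f2)
        assert table.loc["cond", "F"] == pytest.approx(oracle["f1"])
        assert table.loc["incl", "F"] == pytest.approx(oracle["f2"])
        assert table.loc["cond:incl", "F"] == pytest.approx(oracle["interaction"])
        assert table.loc["residual", "df"] == 4 * n - 4

    def test_unbalanced_type3_lstsq_oracle(self):
        rng = np.random.default_rng(7)
        cells = {("FB1", "inc"): 14, ("FB1", "exc"): 6,
                 ("FB2", "inc"): 9, ("FB2", "exc"): 17}
        f1, f2, y = [], [], []
        for (a, b), n in cells.items():
            f1 += [a] * n
            f2 += [b] * n
            y += list(rng.normal(0.5 + (a == "FB1") * 0.1 - (b == "exc") * 0.15, 0.2, n))
        table = anova_2x2_between(y, f1, f2)
        oracle = _type3_lstsq_oracle(y, f1, f2)
        assert table.loc["condition", "F"] == pytest.approx(oracle["f1"])
        assert table.loc["inclusion", "F"] == pytest.approx(oracle["f2"])
        assert table.loc["condition:inclusion", "F"] == pytest.approx(oracle["interaction"])

    def test_equal_cell_means_give_zero_f(self):
        f1 = ["FB1", "FB1", "FB2", "FB2"] * 2
        f2 = ["inc", "exc"] * 4
        y = [0.5] * 6 + [0.4, 0.6]  # variation only inside one cell
        table = anova_2x2_between(y, f1, f2)
        assert table.loc["condition", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_nan_rows_dropped_before_df(self):
        rng = np.random.default_rng(1)
        f1 = ["FB1"] * 10 + ["FB2"] * 10
        f2 = (["inc"] * 5 + ["exc"] * 5) * 2
        y = rng.normal(0.5, 0.1, 20)
        y[3] = np.nan
        table = anova_2x2_between(y, f1, f2)
        assert table.loc["residual", "df"] == 19 - 4

    def test_empty_cell_rejected(self):
        with pytest.raises(StatsError, match="empty cell"):
            anova_2x2_between(
                [0.1, 0.2, 0.3, 0.4],
                ["FB1", "FB1", "FB2", "FB2"],
                ["inc", "inc", "inc", "exc"],
            )


class TestMixedAnova:
    def test_matches_pingouin_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 9
        c = rng.normal(900, 200, 2 * n)
        i = rng.normal(700, 250, 2 * n)
        cond = ["FB1"] * n + ["FB2"] * n
        ours = mixed_anova_duration(c, i, cond)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(2 * n), 2),
                "window": ["correct", "incorrect"] * (2 * n),
                "dur": np.column_stack([c, i]).ravel(),
                "cond": np.repeat(cond, 2),
            }
        )
        theirs = pg.mixed_anova(
            long, dv="dur", within="window", subject="subject", between="cond"
        ).set_index("Source")
        assert ours.loc["condition", "F"] == pytest.approx(theirs.loc["cond", "F"])
        assert ours.loc["window", "F"] == pytest.approx(theirs.loc["window", "F"])
        assert ours.loc["condition:window", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"]
        )
        assert ours.loc["window", "df2"] == 2 * n - 2

    def test_unbalanced_against_regression_oracle(self):
        # Type-III within effect: test of the unweighted grand mean of the
        # difference scores; cross-checked against statsmodels OLS
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        n1, n2 = 11, 5
        c = rng.normal(900, 200, n1 + n2)
        i = rng.normal(750, 220, n1 + n2)
        cond = ["FB1"] * n1 + ["FB2"] * n2
        ours = mixed_anova_duration(c, i, cond)
        d = (c - i) / 2
        fit = smf.ols(
            "d ~ C(g, Sum)", data=pd.DataFrame({"d": d, "g": cond})
        ).fit()
        assert ours.loc["window", "F"] == pytest.approx(fit.tvalues["Intercept"] ** 2)
        assert ours.loc["condition:window", "F"] == pytest.approx(
            fit.tvalues.iloc[1] ** 2
        )

    def test_zero_condition_difference_gives_zero_interaction(self):
        c = np.array([900.0, 950, 800, 860, 900, 950, 800, 860])
        # difference scores vary within groups but have equal group means
        diffs = np.array([80.0, 120, 100, 100, 120, 80, 90, 110])
        i = c - diffs
        cond = ["FB1"] * 4 + ["FB2"] * 4
        table = mixed_anova_duration(c, i, cond)
        assert table.loc["condition:window", "F"] == pytest.approx(0.0, abs=1e-12)
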