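"""Evaluation statistics: detection calls, categories, CV, Wilcoxon, OR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from probemap.evaluate import (
    CATEGORIES,
    ContingencyTable,
    EvalConfig,
    categorize,
    cv,
    expression_status,
    odds_ratio,
    wilcoxon_matched,
)


class TestExpressionStatus:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])

    def test_half_of_four_samples_suffices(self):
        df = self._frame([[0.001, 0.001, 0.5, 0.5]])
        assert expression_status(df).tolist() == [True]

    def test_all_high_not_expressed(self):
        df = self._frame([[0.5, 0.5, 0.5, 0.5]])
        assert expression_status(df).tolist() == [False]

    def test_boundary_p_exactly_threshold_does_not_count(self):
        df = self._frame([[0.01, 0.01, 0.01, 0.01]])
        assert expression_status(df).tolist() == [False]
        df2 = self._frame([[0.00999, 0.00999, 0.5, 0.5]])
        assert expression_status(df2).tolist() == [True]

    def test_fraction_rounds_up(self):
        # 5 samples at fraction 0.5 -> need ceil(2.5) = 3 passing
        df = self._frame([[0.001, 0.001, 0.5, 0.5, 0.5]])
        assert expression_status(df).tolist() == [False]
        df2 = self._frame([[0.001, 0.001, 0.001, 0.5, 0.5]])
        assert expression_status(df2).tolist() == [True]

    def test_hand_count_against_matrix(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(size=(20, 10))
        df = pd.DataFrame(mat, index=[f"p{i}" for i in range(20)])
        got = expression_status(df)
        for i in range(20):
            expect = (mat[i] < 0.01).sum() >= math.ceil(0.5 * 10)
            assert got.iloc[i] == expect

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            expression_status(pd.DataFrame())

    def test_out_of_range_values_rejected(self):
        df = pd.DataFrame([[0.5, 1.5]])
        with pytest.raises(ValueError):
            expression_status(df)


class TestCategorize:
    def test_partition_of_universe(self):
        universe = [f"p{i}" for i in range(100)]
        cats = categorize(
            good_ra=universe[:60], good_rm=universe[30:80],
            repeat_rm=universe[75:90], universe=universe,
        )
        assert len(cats) == 100
        assert set(cats.unique()) <= set(CATEGORIES)

    def test_category_rules(self):
        cats = categorize(
            good_ra={"both", "ra_only", "rep"},
            good_rm={"both", "rm_only"},
            repeat_rm={"rep"},
            universe=["both", "ra_only", "rm_only", "neither", "rep"],
        )
        assert cats["both"] == "Both"
        assert cats["ra_only"] == "InRA"
        assert cats["rm_only"] == "InRM"
        assert cats["neither"] == "None"
        assert cats["rep"] == "InRepeat"  # repeat flag takes precedence


class TestCV:
    def test_constant_vector_zero(self):
        assert cv([3.0, 3.0, 3.0]) == 0.0

    def test_closed_form(self):
        assert cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, size=20)
        assert cv(x * 7.3) == pytest.approx(cv(x))

    def test_zero_mean_undefined(self):
        assert math.isnan(cv([-1.0, 1.0]))

    def test_single_value_undefined(self):
        assert math.isnan(cv([5.0]))


def _enumeration_p(x_vals, pool, n1):
    """Exact two-sided rank-sum p by enumerating all size-n1 subsets."""
    def u_stat(group, rest):
        return sum(
            sum(1.0 if a > b else (0.5 if a == b else 0.0) for b in rest)
            for a in group
        )

    rest_obs = [v for v in pool]
    for v in x_vals:
        rest_obs.remove(v)
    u_obs = u_stat(x_vals, rest_obs)
    us = []
    for combo in itertools.combinations(range(len(pool)), n1):
        grp = [pool[i] for i in combo]
        rest = [pool[i] for i in range(len(pool)) if i not in combo]
        us.append(u_stat(grp, rest))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_small_sample_exact_third(self):
        _, p = wilcoxon_matched([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_null(self):
        _, p = wilcoxon_matched([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_w_is_rank_sum_of_first_group(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.uniform(size=6)
            y = rng.uniform(size=6)
            w, _ = wilcoxon_matched(x, y)
            pooled = np.concatenate([x, y])
            ranks = pd.Series(pooled).rank().to_numpy()
            assert w == pytest.approx(ranks[:6].sum())

    def test_matches_enumeration_all_small_splits(self):
        """Exact p equals subset enumeration for every split of n <= 8."""
        for n in range(3, 9):
            pool = list(range(1, n + 1))
            for n1 in range(1, n):
                for combo in itertools.combinations(pool, n1):
                    x = list(combo)
                    y = [v for v in pool if v not in combo]
                    if not y:
                        continue
                    if len(y) > len(x):
                        # avoid the subsampling path: test the symmetric call
                        continue
                    _, p = wilcoxon_matched(x, y)
                    assert p == pytest.approx(_enumeration_p(x, pool, n1))

    def test_subsampling_matches_group_sizes_and_is_seeded(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=10)
        ref = rng.uniform(size=100)
        w1, p1 = wilcoxon_matched(x, ref, seed=42)
        w2, p2 = wilcoxon_matched(x, ref, seed=42)
        w3, p3 = wilcoxon_matched(x, ref, seed=43)
        assert (w1, p1) == (w2, p2)
        assert (w1, p1) != (w3, p3)

    def test_symmetry_under_group_swap(self):
        x = [1.0, 4.0, 6.0]
        y = [2.0, 3.0, 7.0]
        _, p_xy = wilcoxon_matched(x, y)
        _, p_yx = wilcoxon_matched(y, x)
        assert p_xy == pytest.approx(p_yx)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_matched([], [1.0])


class TestOddsRatio:
    def test_symmetric_table_gives_unity(self):
        or_, lo, hi = odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_row_swap_inverts(self):
        t = ContingencyTable(12, 5, 7, 20)
        or1, _, _ = odds_ratio(t)
        or2, _, _ = odds_ratio(t.swap_rows())
        assert or1 * or2 == pytest.approx(1.0)

    def test_column_swap_inverts(self):
        t = ContingencyTable(12, 5, 7, 20)
        or1, _, _ = odds_ratio(t)
        or2, _, _ = odds_ratio(t.swap_columns())
        assert or1 * or2 == pytest.approx(1.0)

    def test_matches_statsmodels_woolf(self):
        """Independent cross-check of OR and log-method CI."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = ContingencyTable(123, 45, 67, 89)
        table2x2 = sm.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        or_, lo, hi = odds_ratio(t)
        assert or_ == pytest.approx(table2x2.oddsratio)
        sm_lo, sm_hi = table2x2.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo) and hi == pytest.approx(sm_hi)

    def test_zero_cell_haldane_corrected_with_warning(self):
        with pytest.warns(UserWarning, match="Haldane"):
            or_, lo, hi = odds_ratio(ContingencyTable(10, 0, 5, 5))
        assert math.isfinite(or_) and lo < or_ < hi

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestCompareAnnotations:
    def test_full_comparison_is_seed_reproducible(self):
        rng = np.random.default_rng(4)
        probes = [f"p{i}" for i in range(120)]
        expr = pd.DataFrame(
            rng.lognormal(5, 0.2, size=(120, 8)), index=probes
        )
        detp = pd.DataFrame(
            rng.uniform(0, 0.02, size=(120, 8)), index=probes
        )
        good_ra = set(probes[:80])
        good_rm = set(probes[40:100])
        rep = set(probes[110:])
        from probemap.evaluate import compare_annotations

        r1 = compare_annotations(expr, detp, good_ra, good_rm, rep, seed=9)
        r2 = compare_annotations(expr, detp, good_ra, good_rm, rep, seed=9)
        assert r1 == r2
        assert sum(r1["category_sizes"].values()) <= len(probes)
        for tool in ("RA", "RM"):
            t = r1["odds_ratio"][tool]["table"]
            assert t["a"] + t["b"] + t["c"] + t["d"] == len(probes)
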