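"""Statistical layer against independent oracles: enumeration, closed forms,
scipy/statsmodels cross-checks, and planted-signal recovery."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from senoniche.annotation import NormalizedMatrix
from senoniche.stats import (
    IsgPanel,
    bh_adjust,
    fisher_exact_2x2,
    isg_call,
    isg_call_from_clusters,
    isg_score,
    overlap_analysis,
    rank_sum_test,
    run_contrasts,
)


def enumeration_rank_sum_p(a, b):
    """Oracle: full enumeration of the rank-sum null (no ties), doubling rule."""
    pooled = sorted(a) + sorted(b)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in a)
    ws = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), len(a))]
    lo = sum(w <= w_obs for w in ws)
    hi = sum(w >= w_obs for w in ws)
    return min(1.0, 2.0 * min(lo, hi) / len(ws))


def fraction_fisher_p(a, b, c, d):
    """Oracle: exact-rational hypergeometric enumeration of the two-sided p."""
    import math

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k):
        return Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), math.comb(n, r1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


class TestRankSum:
    def test_extreme_split_gives_one_tenth(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0
        assert rank_sum_test([5.0] * 4, [5.0] * 6) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_path_matches_enumeration_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        na = int(rng.integers(1, 7))
        nb = int(rng.integers(1, 13 - na))
        vals = rng.permutation(np.arange(1, na + nb + 1)).astype(float)
        a, b = vals[:na], vals[na:]
        got = rank_sum_test(a, b)
        assert got == pytest.approx(enumeration_rank_sum_p(list(a), list(b)), abs=1e-12)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(float(ref), abs=1e-12)

    def test_normal_approximation_close_to_enumeration_at_n12(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            vals = rng.permutation(np.arange(1, 13)).astype(float)
            a, b = vals[:6], vals[6:]
            exact = enumeration_rank_sum_p(list(a), list(b))
            approx = rank_sum_test(a, b, method="approx")
            assert abs(approx - exact) < 0.02


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_statsmodels_and_is_order_equivariant(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(pvals))
        q_perm = bh_adjust(np.asarray(pvals)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestFisherExact:
    def test_hand_enumerated_table(self):
        p, odds = fisher_exact_2x2(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70, rel=1e-9)
        assert odds == pytest.approx(9.0)

    def test_zero_margin_gives_p_one_and_undefined_odds(self):
        p, odds = fisher_exact_2x2(0, 0, 5, 7)
        assert p == 1.0 and np.isnan(odds)

    def test_infinite_odds_when_off_diagonal_empty(self):
        p, odds = fisher_exact_2x2(4, 1, 0, 5)
        assert np.isinf(odds)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exact_rational_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
            a, b, c, d = (int(v) for v in t)
            if min(a + b, c + d, a + c, b + d) > 0:
                break
        p, _ = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fraction_fisher_p(a, b, c, d), abs=1e-12)


def nm_from_dense(arr, genes):
    arr = np.asarray(arr, dtype=float)
    return NormalizedMatrix(
        values=arr, gene_ids=list(genes),
        cell_ids=np.arange(1, arr.shape[0] + 1), target_sum=1.0,
    )


class TestIsgScore:
    def test_all_zero_cell_scores_zero(self):
        nm = nm_from_dense([[0, 0, 0, 0]], IsgPanel().genes)
        assert isg_score(nm).iloc[0] == 0.0

    def test_constant_panel_scores_constant(self):
        nm = nm_from_dense([[1.0, 1.0, 1.0, 1.0]], IsgPanel().genes)
        assert isg_score(nm).iloc[0] == 1.0

    def test_equals_brute_force_panel_mean_and_sum(self):
        rng = np.random.default_rng(0)
        genes = list(IsgPanel().genes) + ["Alb", "Ttr"]
        vals = rng.random((8, 6))
        nm = nm_from_dense(vals, genes)
        np.testing.assert_allclose(isg_score(nm), vals[:, :4].mean(axis=1))
        np.testing.assert_allclose(isg_score(nm, mode="sum"), vals[:, :4].sum(axis=1))

    def test_no_panel_genes_rejected(self):
        nm = nm_from_dense([[1.0]], ["Alb"])
        with pytest.raises(ValueError, match="panel"):
            isg_score(nm)


class TestIsgCall:
    def test_constant_scores_yield_no_positives(self):
        s = pd.Series(np.full(50, 2.0))
        assert isg_call(s, 0.9).sum() == 0

    def test_order_statistic_count_at_99th_percentile(self):
        s = pd.Series(np.random.default_rng(0).permutation(1000).astype(float))
        assert isg_call(s, 0.99).sum() == 10

    def test_cluster_membership_mode(self):
        cl = pd.Series(["0", "1", "1", "2"])
        assert isg_call_from_clusters(cl, 1).tolist() == [False, True, True, False]

    def test_planted_focus_recovered(self, default_analysis):
        a = default_analysis
        scores = isg_score(a["nm"])
        status = isg_call(scores, threshold_quantile=0.98)
        truth = a["truth"].cells
        hits = n_true = 0
        for sid, pos in status.items():
            tix = a["seg_to_truth"].get(int(sid))
            if tix is None:
                continue
            if truth["is_isg"].iloc[tix]:
                n_true += 1
                hits += bool(pos)
        assert n_true > 0
        assert hits / n_true >= 0.9


class TestRunContrasts:
    @staticmethod
    def separated_case():
        rng = np.random.default_rng(0)
        n = 40
        vals = rng.random((n, 5)) * 0.1
        vals[:10, 0] += 5.0  # gene g0 only in group A
        nm = nm_from_dense(vals, [f"g{i}" for i in range(5)])
        roles = pd.Series(["p21_positive"] * 10 + ["other"] * 30,
                          index=nm.cell_ids, name="niche_role")
        types = pd.Series(["hep"] * n, index=nm.cell_ids, name="cell_type")
        return nm, roles, types

    def test_separating_gene_tops_the_contrast(self):
        nm, roles, types = self.separated_case()
        results = run_contrasts(nm, roles, types)
        r = next(x for x in results if x.contrast == "p21_vs_rest")
        t = r.table.set_index("gene")
        assert t.loc["g0", "log2fc"] > 0
        assert t.loc["g0", "pval"] == t["pval"].min()
        assert bool(t.loc["g0", "significant"])

    def test_underpowered_groups_skipped(self):
        nm, roles, types = self.separated_case()
        roles.iloc[:8] = "other"  # only 2 p21+ cells left
        results = run_contrasts(nm, roles, types, min_cells=3)
        assert all(r.contrast != "p21_vs_rest" for r in results)

    def test_unknown_role_label_rejected(self):
        nm, roles, types = self.separated_case()
        roles.iloc[0] = "mystery"
        with pytest.raises(ValueError, match="role"):
            run_contrasts(nm, roles, types)

    def test_permuted_labels_control_false_positives(self):
        rng = np.random.default_rng(7)
        n, g = 120, 60
        nm = nm_from_dense(rng.random((n, g)), [f"g{i}" for i in range(g)])
        types = pd.Series(["hep"] * n, index=nm.cell_ids)
        fracs = []
        for _ in range(10):
            lab = np.array(["p21_positive"] * 10 + ["other"] * (n - 10))
            roles = pd.Series(rng.permutation(lab), index=nm.cell_ids)
            results = run_contrasts(nm, roles, types)
            r = next(x for x in results if x.contrast == "p21_vs_rest")
            fracs.append(r.table["significant"].mean())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs)) if len(fracs) > 1 else 0.0
        assert np.mean(fracs) <= 0.05 + 3 * se + 1e-12


class TestOverlapAnalysis:
    def test_nested_statuses_are_strongly_dependent(self):
        n = 1000
        p21 = pd.Series([True] * 50 + [False] * (n - 50))
        isg = p21.copy()  # perfectly nested
        rep = pd.Series(["r1"] * n)
        tables, _ = overlap_analysis(p21, isg, rep)
        assert tables[0].fisher_p < 1e-6

    def test_all_double_negative_percentages(self):
        n = 40
        p21 = pd.Series([False] * n)
        isg = pd.Series([False] * n)
        tables, pooled = overlap_analysis(p21, isg, pd.Series(["r1"] * n))
        assert tables[0].fisher_p == 1.0
        got = pooled.set_index("category")["percent"]
        assert got["p21-/ISG-"] == 100.0
        assert got[["p21+/ISG+", "p21+/ISG-", "p21-/ISG+"]].sum() == 0.0

    def test_independent_statuses_rarely_significant(self):
        rng = np.random.default_rng(11)
        n = 5000
        p21 = pd.Series(rng.random(n) < 0.015)
        isg = pd.Series(rng.random(n) < 0.02)
        rep = pd.Series(rng.integers(1, 4, n))
        tables, _ = overlap_analysis(p21, isg, rep)
        assert len(tables) == 3
        assert sum(t.fisher_p > 0.05 for t in tables) >= 2
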