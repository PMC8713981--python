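"""Regulatory classification: normalization, contrasts, FDR, decision table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from allomap import cistrans as ct


def bh_stepup_oracle(p):
    """Direct implementation of the Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(ct.compute_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 100, size=200)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = ct.compute_size_factors(counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            ct.compute_size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))

    def test_total_count_fallback_with_sparse_matrix(self):
        # no gene is expressed everywhere, so median-of-ratios is undefined
        counts = pd.DataFrame({"a": [10, 0, 30, 0] * 20, "b": [0, 20, 0, 40] * 20})
        f = ct.compute_size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
        assert f["b"] > f["a"]

    def test_factors_have_unit_geometric_mean(self, small_panel):
        counts, _, _ = small_panel
        f = ct.compute_size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


class TestLogExpression:
    @pytest.mark.parametrize("count,factor,pseudo,expected", [
        (0, 1.0, 0.5, -1.0),
        (8, 1.0, 0.0, 3.0),
        (10, 2.0, 0.5, np.log2(5.5)),
    ])
    def test_known_values(self, count, factor, pseudo, expected):
        counts = pd.DataFrame({"s": [count]})
        out = ct.log_expression(counts, pd.Series({"s": factor}), pseudo)
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            ct.log_expression(pd.DataFrame({"s": [1]}), pd.Series({"s": 0.0}))


class TestContrast:
    def _mat(self, a_vals, b_vals):
        data = {f"a{i}": [v] for i, v in enumerate(a_vals)}
        data.update({f"b{i}": [v] for i, v in enumerate(b_vals)})
        return (pd.DataFrame(data), [f"a{i}" for i in range(len(a_vals))],
                [f"b{i}" for i in range(len(b_vals))])

    def test_identical_groups_null(self):
        mat, ga, gb = self._mat([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        res = ct.estimate_contrast(mat, ga, gb)
        assert res["L"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_separated_constant_groups_significant(self):
        mat, ga, gb = self._mat([5.0, 5.0, 5.0], [3.0, 3.0, 3.0])
        res = ct.estimate_contrast(mat, ga, gb)
        assert res["L"].iloc[0] == pytest.approx(2.0)
        assert res["p"].iloc[0] < 0.05

    def test_matches_welch_ttest(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(50, 8)),
                           columns=[f"s{i}" for i in range(8)])
        ga, gb = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        res = ct.estimate_contrast(mat, ga, gb, variance_floor_quantile=0.0)
        ref = stats.ttest_ind(mat[ga], mat[gb], axis=1, equal_var=False)
        assert np.allclose(res["p"], ref.pvalue)

    def test_swapping_groups_negates_effect(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(20, 6)),
                           columns=[f"s{i}" for i in range(6)])
        ga, gb = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]
        r1 = ct.estimate_contrast(mat, ga, gb)
        r2 = ct.estimate_contrast(mat, gb, ga)
        assert np.allclose(r1["L"], -r2["L"])
        assert np.allclose(r1["p"], r2["p"])

    def test_small_group_rejected(self):
        mat, ga, gb = self._mat([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2"):
            ct.estimate_contrast(mat, ga, gb)


class TestTransTest:
    def test_equal_effects_are_null(self):
        res = ct.test_trans([1.5], [0.1], [1.5], [0.2])
        assert res["T"].iloc[0] == 0.0 and res["p_T"].iloc[0] == 1.0

    def test_known_z_score(self):
        res = ct.test_trans([2.0], [0.1], [0.0], [0.1])
        assert res["T"].iloc[0] == pytest.approx(2.0)
        assert res["SE_T"].iloc[0] == pytest.approx(np.sqrt(0.02))
        z = 2.0 / np.sqrt(0.02)
        assert z == pytest.approx(14.142, abs=0.01)
        assert res["p_T"].iloc[0] == pytest.approx(2 * stats.norm.sf(z))

    def test_negation_symmetric(self):
        r1 = ct.test_trans([1.2], [0.3], [0.4], [0.2])
        r2 = ct.test_trans([-1.2], [0.3], [-0.4], [0.2])
        assert r1["T"].iloc[0] == -r2["T"].iloc[0]
        assert r1["p_T"].iloc[0] == r2["p_T"].iloc[0]

    def test_degenerate_zero_se(self):
        res = ct.test_trans([1.0], [0.0], [0.0], [0.0])
        assert res["p_T"].iloc[0] == 0.0


class TestBH:
    def test_singleton(self):
        assert ct.adjust_bh([0.01])[0] == pytest.approx(0.01)

    def test_stepup_example(self):
        assert np.allclose(ct.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(ct.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates(self):
        q = ct.adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_matches_stepup_oracle(self, p):
        assert np.allclose(ct.adjust_bh(p), bh_stepup_oracle(p))

    def test_matches_oracle_large_random(self):
        rng = np.random.default_rng(3)
        p = rng.random(1000)
        assert np.allclose(ct.adjust_bh(p), bh_stepup_oracle(p))


class TestDecisionTable:
    def test_full_enumeration(self):
        """All 8 significance patterns x sign combinations map as documented."""
        for sde, sase, st_ in itertools.product([False, True], repeat=3):
            for c_sign, t_sign in itertools.product([-1.0, 0.0, 1.0], repeat=2):
                q_de = 0.01 if sde else 0.5
                q_ase = 0.01 if sase else 0.5
                q_t = 0.01 if st_ else 0.5
                got = ct.classify_regulatory([q_de], [q_ase], [q_t],
                                             [c_sign], [t_sign])[0]
                if not sde and not sase and not st_:
                    expected = "conserved"
                elif not sde and sase and st_:
                    expected = "compensatory"
                elif sde and sase and not st_:
                    expected = "cis"
                elif sde and not sase and st_:
                    expected = "trans"
                elif sde and sase and st_:
                    agree = c_sign == t_sign or c_sign == 0 or t_sign == 0
                    expected = "cis+trans" if agree else "cis-trans"
                else:
                    expected = "ambiguous"
                assert got == expected, (sde, sase, st_, c_sign, t_sign)

    def test_boundary_not_significant(self):
        # q exactly alpha is not significant
        got = ct.classify_regulatory([0.05], [0.05], [0.05], [1.0], [1.0], alpha=0.05)
        assert got[0] == "conserved"


class TestClassifyAll:
    def test_categories_partition_genes(self, small_panel):
        counts, samples, _ = small_panel
        res = ct.classify_all(counts, samples)
        assert res.summary["n_genes"].sum() == len(counts)
        assert set(res.calls["category"]) <= set(ct.CATEGORIES)

    def test_cis_plus_trans_identity(self, small_panel):
        counts, samples, _ = small_panel
        res = ct.classify_all(counts, samples)
        assert np.allclose(res.effects["L_ASE"] + res.effects["T"],
                           res.effects["L_DE"], atol=1e-12)

    def test_species_label_swap_negates_effects_keeps_calls(self, small_panel):
        counts, samples, _ = small_panel
        res1 = ct.classify_all(counts, samples)
        flipped = samples.copy()
        swap = {"human_parental": "chimp_parental",
                "chimp_parental": "human_parental",
                "hybrid_human_allele": "hybrid_chimp_allele",
                "hybrid_chimp_allele": "hybrid_human_allele"}
        flipped["context"] = flipped["context"].map(swap)
        res2 = ct.classify_all(counts, flipped)
        assert np.allclose(res1.effects["L_DE"], -res2.effects["L_DE"])
        assert np.allclose(res1.effects["L_ASE"], -res2.effects["L_ASE"])
        assert np.allclose(res1.effects["T"], -res2.effects["T"])
        assert (res1.calls["category"] == res2.calls["category"]).all()

    def test_missing_context_rejected(self, small_panel):
        counts, samples, _ = small_panel
        broken = samples[samples["context"] != "chimp_parental"]
        with pytest.raises(ValueError, match="chimp_parental"):
            ct.classify_all(counts[broken["sample_id"]], broken)


class TestTwofoldFilter:
    def test_boundary_inclusive(self):
        effects = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                                "L_DE": [1.0, 0.99, -1.2]})
        calls = pd.DataFrame({"gene_id": effects["gene_id"]})
        kept = ct.filter_twofold(calls, effects, threshold=1.0)
        assert list(kept) == ["g1", "g3"]
        assert len(ct.filter_twofold(calls, effects, threshold=0.0)) == 3


class TestEffectSizeComparison:
    def test_exact_small_sample_p(self):
        res = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided")
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 100), unique=True, min_size=4, max_size=16),
           st.integers(2, 14))
    def test_scipy_matches_enumeration_oracle(self, pooled, cut):
        # tie-free data, group sizes <= 8: scipy's exact method should agree
        # with full enumeration of group assignments
        cut = min(max(cut, 2), len(pooled) - 2)
        a, b = pooled[:cut], pooled[cut:]
        if len(a) > 8 or len(b) > 8:
            a, b = a[:8], b[:8]
        if len(a) < 2 or len(b) < 2:
            return
        got = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(ct.mannwhitney_exact_oracle(a, b), abs=1e-9)

    def test_category_stats_and_identical_pair(self):
        calls = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(12)],
            "category": ["cis"] * 4 + ["trans"] * 4 + ["conserved"] * 4,
        })
        effects = pd.DataFrame({
            "gene_id": calls["gene_id"],
            "L_DE": [1.0, 2.0, 3.0, 4.0] * 2 + [0.1, 0.2, 0.3, 0.4],
        })
        per_cat, pairwise = ct.compare_effect_sizes(calls, effects)
        cis = per_cat[per_cat["category"] == "cis"].iloc[0]
        assert cis["median_abs_lfc"] == pytest.approx(np.median([1, 2, 3, 4]))
        row = pairwise[(pairwise["category_a"] == "cis")
                       & (pairwise["category_b"] == "trans")].iloc[0]
        assert row["p"] == pytest.approx(1.0)

    def test_singleton_category_excluded(self):
        calls = pd.DataFrame({"gene_id": ["g0", "g1", "g2", "g3"],
                              "category": ["cis", "trans", "trans", "trans"]})
        effects = pd.DataFrame({"gene_id": calls["gene_id"],
                                "L_DE": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            ct.compare_effect_sizes(calls, effects)


class TestAnnotationBurden:
    def _setup(self, cis_burden, conserved_burden, n=40):
        genes = [f"g{i}" for i in range(2 * n)]
        calls = pd.DataFrame({"gene_id": genes,
                              "category": ["cis"] * n + ["conserved"] * n})
        effects = pd.DataFrame({"gene_id": genes, "L_DE": [2.0] * n + [0.0] * n})
        burden = pd.Series(list(cis_burden) + list(conserved_burden), index=genes)
        return calls, effects, burden

    def test_constant_burden_is_null(self):
        calls, effects, burden = self._setup([7] * 40, [7] * 40)
        out = ct.annotation_burden_test(calls, effects, burden)
        assert out["median_burden"].iloc[0] == out.attrs["conserved_median"] == 7
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_smaller_burden_detected(self):
        rng = np.random.default_rng(4)
        calls, effects, burden = self._setup(
            rng.poisson(15, 200), rng.poisson(30, 200), n=200)
        out = ct.annotation_burden_test(calls, effects, burden)
        row = out[out["category"] == "cis"].iloc[0]
        assert row["median_burden"] < out.attrs["conserved_median"]
        assert row["q"] < 0.05

    def test_gene_missing_from_burden_excluded(self):
        calls, effects, burden = self._setup([5] * 40, [5] * 40)
        burden = burden.drop("g0")
        out = ct.annotation_burden_test(calls, effects, burden)
        assert out["n"].iloc[0] == 39

    def test_small_filtered_category_skipped(self):
        genes = [f"g{i}" for i in range(43)]
        calls = pd.DataFrame({"gene_id": genes,
                              "category": ["cis"] * 3 + ["conserved"] * 40})
        effects = pd.DataFrame({"gene_id": genes, "L_DE": [2.0] * 3 + [0.0] * 40})
        burden = pd.Series(5, index=genes)
        out = ct.annotation_burden_test(calls, effects, burden, min_genes=6)
        assert "cis" not in set(out["category"])
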