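"""Category enrichment with spatial ensemble nulls and weighted-KS GSEA:
scores, running sums and null calibration against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import braintx as bx
from braintx.errors import DegenerateSetError, ParameterError
from tests_oracles import bh_oracle, gsea_es_oracle  # see tests/tests_oracles.py


class TestGeneScores:
    def test_direction_transforms(self, table_factory):
        table = table_factory([0.865, -0.3])
        pos = bx.gene_scores(table, "positive")
        neg = bx.gene_scores(table, "negative")
        absx = bx.gene_scores(table, "absolute")
        rho = table.rho_series()
        hi = rho.idxmax()
        lo = rho.idxmin()
        assert pos[hi] == pytest.approx(0.865) and pos[lo] == 0.0
        assert neg[lo] == pytest.approx(0.3) and neg[hi] == 0.0
        assert absx[lo] == pytest.approx(0.3)

    def test_unknown_direction_rejected(self, table_factory):
        with pytest.raises(ParameterError):
            bx.gene_scores(table_factory([0.1, 0.2]), "sideways")


class TestBHAdjustment:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_direct_oracle(self, ps):
        np.testing.assert_allclose(bx.bh_adjust(ps), bh_oracle(ps), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (bx.bh_adjust(p) >= p - 1e-15).all()


class TestGSEAES:
    def test_hand_computed_four_gene_case(self, table_factory):
        # descending rhos (0.8, 0.6, 0.4, 0.2), set = ranks {1, 3}, w = 1:
        # running sum (2/3, 1/6, 1/2, 0) -> ES = 2/3
        table = table_factory([0.8, 0.6, 0.4, 0.2])
        genes = table.gene_ids
        res = bx.gsea_es(table, {genes[0], genes[2]}, weight_exponent=1.0)
        np.testing.assert_allclose(
            res.es_curve, [2 / 3, 1 / 6, 1 / 2, 0], atol=1e-12
        )
        assert res.es == pytest.approx(2 / 3)
        assert res.max_position == 1

    def test_top_genes_give_es_one(self, table_factory):
        rng = np.random.default_rng(1)
        table = table_factory(rng.uniform(0.1, 1, 30))
        top = set(table.gene_ids[:7])
        assert bx.gsea_es(table, top).es == pytest.approx(1.0)

    def test_bottom_genes_give_negative_es(self, table_factory):
        rng = np.random.default_rng(2)
        table = table_factory(rng.uniform(0.1, 1, 30))
        bottom = set(table.gene_ids[-7:])
        assert bx.gsea_es(table, bottom).es < 0

    def test_curve_is_conserved_and_matches_oracle(self, table_factory):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            table = table_factory(rng.uniform(-1, 1, n))
            m = int(rng.integers(1, n))
            gene_set = set(rng.choice(table.gene_ids, size=m, replace=False))
            w = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            res = bx.gsea_es(table, gene_set, weight_exponent=w)
            es_o, curve_o = gsea_es_oracle(
                table.data["rho"].to_numpy(),
                np.array([g in gene_set for g in table.gene_ids]),
                w,
            )
            np.testing.assert_allclose(res.es_curve, curve_o, atol=1e-12)
            assert res.es == pytest.approx(es_o, abs=1e-12)
            assert abs(res.es_curve[-1]) < 1e-12

    def test_unweighted_equals_classic_ks_statistic(self, table_factory):
        # w = 0: ES is the max deviation between the two ECDFs of set and
        # non-set rank positions (classic two-sample KS)
        rng = np.random.default_rng(4)
        table = table_factory(rng.uniform(-1, 1, 50))
        gene_set = set(rng.choice(table.gene_ids, size=12, replace=False))
        res = bx.gsea_es(table, gene_set, weight_exponent=0.0)
        member = np.array([g in gene_set for g in table.gene_ids])
        pos = np.arange(1, 51)
        ecdf_hit = np.cumsum(member) / member.sum()
        ecdf_miss = np.cumsum(~member) / (~member).sum()
        diffs = ecdf_hit - ecdf_miss
        assert abs(res.es) == pytest.approx(np.max(np.abs(diffs)), abs=1e-12)

    @pytest.mark.parametrize("bad", [set(), "all"])
    def test_degenerate_sets_rejected(self, table_factory, bad):
        table = table_factory([0.5, 0.2, -0.1])
        gene_set = set(table.gene_ids) if bad == "all" else bad
        with pytest.raises(DegenerateSetError):
            bx.gsea_es(table, gene_set)


class TestGSEAPValue:
    def test_random_sets_give_uniformish_p(self, table_factory):
        rng = np.random.default_rng(5)
        ps = []
        for i in range(200):
            table = table_factory(rng.uniform(-1, 1, 50))
            gene_set = set(rng.choice(table.gene_ids, size=8, replace=False))
            ps.append(bx.gsea_pvalue(table, gene_set, n_perm=100, seed=i).p)
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert np.mean(ps < 0.05) < 0.12

    def test_planted_top_set_is_significant(self, table_factory):
        rng = np.random.default_rng(6)
        table = table_factory(np.sort(rng.uniform(-1, 1, 80))[::-1])
        top = set(table.gene_ids[:10])
        assert bx.gsea_pvalue(table, top, n_perm=500, seed=0).p < 0.05

    def test_observed_below_all_nulls_gives_p_one(self, table_factory):
        # alternating membership yields a tiny |ES|; nulls almost surely beat it
        rhos = np.linspace(1, -1, 100)
        table = table_factory(rhos)
        gene_set = set(table.gene_ids[::2])
        res = bx.gsea_pvalue(table, gene_set, n_perm=200, seed=1)
        assert res.p > 0.9


class TestGCEA:
    def test_planted_category_most_significant(self, small_world, cortex_table):
        table, prof = cortex_table
        scores = bx.gene_scores(table, "positive")
        res = bx.gcea(
            scores,
            small_world["categories"],
            prof,
            small_world["expression"],
            n_nulls=200,
            seed=0,
        )
        truth = small_world["truth"]
        assert res.iloc[0]["category_id"] == truth.planted_category_id
        assert res.iloc[0]["p_cor"] < 0.05

    def test_null_activation_gives_uniform_praw(self):
        # fresh independent activation: category p_raw ~ uniform
        fracs = []
        for seed in range(10):
            cfg = bx.SyntheticConfig(
                n_genes=150, n_regions_cortex=40, n_regions_subcortex=5,
                grid_shape=(12, 12, 8), planted_effect=0.0,
                n_categories=30, category_size_range=(5, 20), seed=seed,
            )
            atlas = bx.generate_atlas(cfg)
            expr = bx.generate_expression(cfg, atlas)
            act, truth = bx.generate_activation(cfg, expr, atlas)
            cats, _, _ = bx.generate_annotations(cfg, truth)
            prof = bx.split_profile(act, atlas, "cortex")
            table = bx.correlate_genes(expr.loc[:, prof.unit_ids], prof)
            res = bx.gcea(
                bx.gene_scores(table, "positive"), cats, prof, expr,
                n_nulls=100, seed=seed,
            )
            fracs.append(np.mean(res["p_raw"] < 0.05))
        assert 0.0 <= np.mean(fracs) < 0.09

    def test_zero_score_category_is_never_enriched(self, small_world, cortex_table):
        table, prof = cortex_table
        scores = bx.gene_scores(table, "positive").copy()
        dead = list(scores.index[:5])
        scores.loc[dead] = 0.0
        res = bx.gcea(
            scores,
            {"dead_cat": dead, **small_world["categories"]},
            prof,
            small_world["expression"],
            n_nulls=100,
            seed=1,
        )
        p = res.set_index("category_id").loc["dead_cat", "p_raw"]
        assert p >= 0.95

    def test_invariant_to_relabeling_unannotated_genes(self, small_world, cortex_table):
        table, prof = cortex_table
        scores = bx.gene_scores(table, "positive")
        cats = {
            k: v for k, v in list(small_world["categories"].items())[:4]
        }
        res1 = bx.gcea(scores, cats, prof, small_world["expression"], n_nulls=100, seed=2)
        # permute identities of genes not in any tested category
        annotated = set().union(*cats.values())
        free = [g for g in scores.index if g not in annotated]
        mapping = dict(zip(free, np.random.default_rng(0).permutation(free)))
        expr2 = small_world["expression"].rename(index=mapping)
        scores2 = scores.rename(index=mapping)
        res2 = bx.gcea(scores2, cats, prof, expr2, n_nulls=100, seed=2)
        merged = res1.merge(res2, on="category_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_raw_a"], merged["p_raw_b"], atol=1e-12)

    def test_no_category_in_size_window_warns_empty(self, small_world, cortex_table):
        table, prof = cortex_table
        res = bx.gcea(
            bx.gene_scores(table, "positive"),
            {"tiny": list(small_world["expression"].index[:2])},
            prof,
            small_world["expression"],
            n_nulls=100,
            seed=3,
        )
        assert len(res) == 0
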