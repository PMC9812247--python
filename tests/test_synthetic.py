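"""The generator must produce fields with the spatial and planted structure
the downstream analysis assumes."""

import numpy as np
import pytest

import braintx as bx
from braintx.errors import ParameterError, SizingError
from braintx.synthetic import planted_gene_ids


class TestAtlas:
    def test_small_grid_fully_labeled_with_nonempty_parcels(self):
        cfg = bx.SyntheticConfig(
            n_genes=5, n_regions_cortex=2, n_regions_subcortex=2,
            grid_shape=(6, 6, 6), category_size_range=(2, 4),
        )
        atlas = bx.generate_atlas(cfg)
        assert set(np.unique(atlas.labels)) == {1, 2, 3, 4}
        assert (atlas.regions["n_voxels"] > 0).all()
        # centroids inside the grid (mm)
        upper = np.array(cfg.grid_shape) * np.array(cfg.voxel_size)
        c = atlas.regions[["x", "y", "z"]].to_numpy()
        assert (c >= 0).all() and (c <= upper).all()
        assert set(atlas.regions["compartment"]) == {"cortex", "subcortex"}

    def test_same_seed_reproduces_label_volume(self):
        cfg = bx.SyntheticConfig(
            n_genes=5, n_regions_cortex=4, n_regions_subcortex=2,
            grid_shape=(8, 8, 6), category_size_range=(2, 4),
        )
        a, b = bx.generate_atlas(cfg), bx.generate_atlas(cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_more_regions_than_voxels_is_sizing_error(self):
        cfg = bx.SyntheticConfig(
            n_genes=5, n_regions_cortex=500, n_regions_subcortex=2,
            grid_shape=(4, 4, 4), category_size_range=(2, 4),
        )
        with pytest.raises(SizingError):
            bx.generate_atlas(cfg)


class TestExpression:
    def test_fixed_seed_bitwise_identical(self, small_config):
        atlas = bx.generate_atlas(small_config)
        a = bx.generate_expression(small_config, atlas)
        b = bx.generate_expression(small_config, atlas)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_near_zero_correlation_length_gives_flat_variogram(self):
        # iid limit: semivariance equals the sill (field variance) everywhere
        cfg = bx.SyntheticConfig(
            n_genes=300, n_regions_cortex=40, n_regions_subcortex=5,
            grid_shape=(12, 12, 8), correlation_length=1e-6, seed=3,
        )
        atlas = bx.generate_atlas(cfg)
        expr = bx.generate_expression(cfg, atlas)
        ids = atlas.region_ids("cortex")
        coords = atlas.centroids("cortex")
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        vals = expr.loc[:, ids].to_numpy()
        vgs = [bx.compute_variogram(v, d) for v in vals[:100]]
        gammas = np.stack([v.gamma for v in vgs]).mean(axis=0)
        sill = vals.var()
        well_sampled = vgs[0].n_pairs >= 20  # few-pair bins are too noisy
        assert np.all(np.abs(gammas[well_sampled] - sill) / sill < 0.15)

    def test_long_correlation_length_near_pairs_correlate_more(self):
        # Monte Carlo over >=200 genes: neighboring regions' expression
        # values are more alike than distant regions'
        cfg = bx.SyntheticConfig(
            n_genes=250, n_regions_cortex=40, n_regions_subcortex=5,
            grid_shape=(12, 12, 8), correlation_length=12.0, seed=4,
        )
        atlas = bx.generate_atlas(cfg)
        expr = bx.generate_expression(cfg, atlas)
        ids = atlas.region_ids("cortex")
        coords = atlas.centroids("cortex")
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        vals = expr.loc[:, ids].to_numpy()
        corr = np.corrcoef(vals.T)
        iu = np.triu_indices(len(ids), k=1)
        near = corr[iu][d[iu] < np.quantile(d[iu], 0.1)]
        far = corr[iu][d[iu] > np.quantile(d[iu], 0.9)]
        assert near.mean() > far.mean() + 0.2

    def test_variogram_increases_then_plateaus(self, small_world):
        prof = bx.split_profile(
            small_world["activation"], small_world["atlas"], "cortex"
        )
        vg = bx.compute_variogram(prof)
        # rising short-range, plateau near the field variance
        assert vg.gamma[0] < vg.gamma[-5:].mean()
        sill = prof.values.var()
        assert abs(vg.gamma[-5:].mean() - sill) / sill < 0.6


class TestActivation:
    def test_single_planted_gene_no_noise_is_monotone_image(self):
        cfg = bx.SyntheticConfig(
            n_genes=50, n_regions_cortex=20, n_regions_subcortex=5,
            grid_shape=(10, 10, 8), planted_gene_fraction=1 / 50,
            planted_effect=1.0, noise_sd=0.0, seed=5,
        )
        atlas = bx.generate_atlas(cfg)
        expr = bx.generate_expression(cfg, atlas)
        act, truth = bx.generate_activation(cfg, expr, atlas)
        (gene,) = truth.planted_gene_ids
        rho = bx.spearman(
            expr.loc[gene, act.unit_ids].to_numpy(), act.values
        )
        assert rho == pytest.approx(1.0)

    def test_zero_effect_levels_planted_and_nonplanted(self):
        # planted_effect = 0: |rho| distributions indistinguishable
        planted_abs, other_abs = [], []
        for seed in range(6):
            cfg = bx.SyntheticConfig(
                n_genes=120, n_regions_cortex=40, n_regions_subcortex=5,
                grid_shape=(12, 12, 8), planted_effect=0.0, seed=seed,
            )
            atlas = bx.generate_atlas(cfg)
            expr = bx.generate_expression(cfg, atlas)
            act, truth = bx.generate_activation(cfg, expr, atlas)
            prof = bx.split_profile(act, atlas, "cortex")
            tab = bx.correlate_genes(expr.loc[:, prof.unit_ids], prof)
            rho = tab.rho_series().abs()
            planted = list(truth.planted_gene_ids)
            planted_abs.extend(rho.loc[planted])
            other_abs.extend(rho.drop(planted))
        assert abs(np.mean(planted_abs) - np.mean(other_abs)) < 0.05

    def test_planted_genes_outrank_others_at_strong_effect(self):
        # planted_effect 0.8, noise 0.2: planted mean |rho| clearly higher
        wins = 0
        for seed in range(20):
            cfg = bx.SyntheticConfig(
                n_genes=100, n_regions_cortex=50, n_regions_subcortex=5,
                grid_shape=(14, 14, 8), planted_effect=0.8, noise_sd=0.2,
                seed=seed,
            )
            atlas = bx.generate_atlas(cfg)
            expr = bx.generate_expression(cfg, atlas)
            act, truth = bx.generate_activation(cfg, expr, atlas)
            prof = bx.split_profile(act, atlas, "cortex")
            tab = bx.correlate_genes(expr.loc[:, prof.unit_ids], prof)
            rho = tab.rho_series().abs()
            planted = list(truth.planted_gene_ids)
            wins += rho.loc[planted].mean() > rho.drop(planted).mean()
        assert wins == 20

    def test_empty_planted_set_rejected(self, small_world):
        cfg = small_world["config"]
        with pytest.raises(ParameterError):
            bx.generate_activation(
                cfg, small_world["expression"], small_world["atlas"], planted=()
            )


class TestAnnotations:
    def test_planted_category_has_highest_jaccard_with_planted_genes(
        self, small_world
    ):
        truth = small_world["truth"]
        planted = set(truth.planted_gene_ids)

        def jaccard(members):
            s = set(members)
            return len(s & planted) / len(s | planted)

        scores = {c: jaccard(m) for c, m in small_world["categories"].items()}
        assert max(scores, key=scores.get) == truth.planted_category_id

    def test_motif_rankings_are_permutations(self, small_world):
        db = small_world["db"]
        n = db.ranks.shape[1]
        for motif in db.motif_ids:
            assert np.array_equal(
                np.sort(db.ranks.loc[motif].to_numpy()), np.arange(1, n + 1)
            )

    def test_nonplanted_motifs_rank_planted_genes_uniformly(self, small_world):
        db = small_world["db"]
        truth = small_world["truth"]
        planted = list(truth.planted_gene_ids)
        planted_motifs = {
            m for m in db.motif_ids
            if db.regulators[m] == truth.planted_regulator_id
        }
        null = [m for m in db.motif_ids if m not in planted_motifs]
        mean_rank = np.mean(
            [db.ranks.loc[m, planted].mean() for m in null]
        )
        n = db.ranks.shape[1]
        # uniform expectation (n+1)/2, Monte Carlo tolerance
        assert abs(mean_rank - (n + 1) / 2) < 0.1 * n

    def test_risk_list_contains_planted_regulator(self, small_world):
        assert (
            small_world["truth"].planted_regulator_id
            in small_world["risk_genes"]
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"planted_gene_fraction": 1.5},
            {"noise_sd": -0.1},
            {"correlation_length": 0.0},
            {"n_regions_cortex": 1},
            {"category_size_range": (1, 5)},
            {"category_size_range": (5, 10_000)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            bx.SyntheticConfig(**kwargs)

    def test_planted_ids_deterministic(self, small_config):
        assert planted_gene_ids(small_config) == planted_gene_ids(small_config)


class TestVoxelPainting:
    def test_region_means_recover_generating_values(self, small_world):
        from braintx.synthetic import expression_volumes

        expr = small_world["expression"].iloc[:3]
        vols = expression_volumes(
            small_world["config"], small_world["atlas"], expr
        )
        atlas = small_world["atlas"]
        for gene, vol in vols.items():
            for rid in atlas.regions["region_id"]:
                mean = vol.values[atlas.labels == rid].mean()
                assert mean == pytest.approx(expr.at[gene, rid], abs=1e-10)
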