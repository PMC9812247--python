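"""Variogram estimation and surrogate generation: the nulls must preserve
spatial autocorrelation while destroying the map's alignment with anything
else."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import braintx as bx
from braintx.correlate import spearman_matrix
from braintx.errors import GeometryError, ParameterError
from braintx.synthetic import _grf_factor


def grid_coords(n, spacing=3.0, seed=0):
    """Scattered 3-D coordinates with a reproducible layout."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0, spacing * n ** (1 / 3) * 2, size=(n, 3))


def distm(coords):
    return np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))


class TestVariogram:
    def test_constant_profile_has_zero_gamma(self):
        coords = grid_coords(30)
        vg = bx.compute_variogram(np.full(30, 2.0), distm(coords))
        np.testing.assert_allclose(vg.gamma, 0.0)

    def test_single_pair_bin_is_half_squared_difference(self):
        # three units; the pair at distance d12 contributes gamma = 0.5*(2)^2
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [10.0, 0, 0]])
        values = np.array([0.0, 2.0, 0.0])
        vg = bx.compute_variogram(values, distm(coords), n_lags=30, max_frac=1.0)
        # the smallest-lag bin contains only the (0,1) pair
        assert vg.gamma[0] == pytest.approx(2.0)
        assert vg.n_pairs[0] == 1

    def test_iid_values_flat_at_unit_sill(self):
        rng = np.random.default_rng(4)
        coords = grid_coords(200, seed=5)
        gammas = np.stack(
            [
                bx.compute_variogram(rng.standard_normal(200), distm(coords)).gamma
                for _ in range(40)
            ]
        )
        mean_gamma = gammas.mean(axis=0)
        se = gammas.std(axis=0) / np.sqrt(len(gammas))
        assert np.all(np.abs(mean_gamma - 1.0) < 3 * se + 0.05)

    def test_colocated_units_is_geometry_error(self):
        with pytest.raises(GeometryError):
            bx.compute_variogram(np.arange(4.0), np.zeros((4, 4)))


@pytest.fixture(scope="module")
def smooth_field():
    # parcellation-centroid geometry (the method's actual use case)
    atlas = bx.generate_atlas(bx.SyntheticConfig())
    coords = atlas.centroids("cortex")
    d = distm(coords)
    L = _grf_factor(coords, np.max(d) * 0.3)
    values = L @ np.random.default_rng(8).standard_normal(len(coords))
    return values, d


class TestSurrogateGeneration:

    def test_deterministic_under_seed(self, smooth_field):
        values, d = smooth_field
        a = bx.generate_surrogates(values, d, k_neighbors=15, n_surrogates=10, seed=3)
        b = bx.generate_surrogates(values, d, k_neighbors=15, n_surrogates=10, seed=3)
        np.testing.assert_array_equal(a.surrogates, b.surrogates)

    def test_k_at_least_n_units_rejected(self, smooth_field):
        values, d = smooth_field
        with pytest.raises(ParameterError):
            bx.generate_surrogates(values, d, k_neighbors=100, n_surrogates=5)

    def test_rank_remap_preserves_value_multiset(self, smooth_field):
        values, d = smooth_field
        ens = bx.generate_surrogates(
            values, d, k_neighbors=15, n_surrogates=20, seed=4, rank_remap=True
        )
        target = np.sort(values)
        for s in ens.surrogates:
            np.testing.assert_allclose(np.sort(s), target)

    def test_surrogates_match_empirical_variogram(self, smooth_field):
        # ensemble-averaged surrogate variogram tracks the empirical one;
        # single surrogates fluctuate as much as fresh field realizations do
        values, d = smooth_field
        vg = bx.compute_variogram(values, d)
        ens = bx.generate_surrogates(values, d, k_neighbors=15, n_surrogates=100, seed=5)
        mean_gamma = np.mean(
            [bx.compute_variogram(s, d).gamma for s in ens.surrogates], axis=0
        )
        assert np.mean(np.abs(mean_gamma - vg.gamma) / vg.gamma) < 0.25

    def test_surrogates_keep_morans_i_where_permutations_do_not(self, smooth_field):
        values, d = smooth_field
        src_moran = bx.morans_i(values, d)
        ens = bx.generate_surrogates(values, d, k_neighbors=15, n_surrogates=50, seed=6)
        surr_moran = np.mean([bx.morans_i(s, d) for s in ens.surrogates])
        rng = np.random.default_rng(7)
        perm_moran = np.mean(
            [bx.morans_i(rng.permutation(values), d) for _ in range(50)]
        )
        assert abs(surr_moran - src_moran) < 0.35 * abs(src_moran)
        assert abs(perm_moran) < 0.25 * src_moran

    def test_iid_source_surrogates_behave_like_permutations(self):
        # no autocorrelation to preserve: surrogate-vs-source correlations
        # should be indistinguishable from a plain permutation null
        coords = grid_coords(80, seed=9)
        d = distm(coords)
        src = np.random.default_rng(10).standard_normal(80)
        ens = bx.generate_surrogates(src, d, k_neighbors=15, n_surrogates=500, seed=11)
        rho_surr = bx.ensemble_correlations(ens, src)
        rng = np.random.default_rng(12)
        perms = src[np.argsort(rng.random((500, 80)), axis=1)]
        rho_perm = spearman_matrix(perms, src)
        assert ks_2samp(np.abs(rho_surr), np.abs(rho_perm)).pvalue > 0.01

    def test_pilot_and_full_scale_search_agree_statistically(self, smooth_field):
        values, d = smooth_field
        fast = bx.generate_surrogates(values, d, k_neighbors=15, n_surrogates=50, seed=13)
        full = bx.generate_surrogates(
            values, d, k_neighbors=15, n_surrogates=50, seed=13, pilot=None
        )
        vg = bx.compute_variogram(values, d)

        def mean_dev(ens):
            return np.mean(
                [
                    np.mean(np.abs(bx.compute_variogram(s, d).gamma - vg.gamma) / vg.gamma)
                    for s in ens.surrogates
                ]
            )

        assert abs(mean_dev(fast) - mean_dev(full)) < 0.1


class TestSpatialPValue:
    def test_literal_proportion_with_strict_inequality(self):
        assert bx.spatial_pvalue(0.5, [0.6, 0.4, 0.3, 0.7]) == pytest.approx(0.5)

    def test_zero_observed_against_nonzero_surrogates_is_one(self):
        assert bx.spatial_pvalue(0.0, [0.1, -0.2, 0.05]) == 1.0

    def test_empty_surrogates_rejected(self):
        with pytest.raises(ParameterError):
            bx.spatial_pvalue(0.5, [])

    def test_zero_p_formatted_as_bound(self):
        from braintx.surrogates import format_p_value

        assert format_p_value(0.0, 1000) == "<0.001"
        assert format_p_value(0.25, 1000) == "0.25"
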