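"""Ground-truth behaviour of the synthetic-data generators."""

import dataclasses

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

import cortexmeta as cm
from cortexmeta.simulate import simple_structure_loadings, simulate_area_cohort


class TestAutocorrelatedMaps:
    def test_deterministic_given_seed(self, ico4):
        a = cm.simulate_autocorrelated_map(ico4, 20.0, seed=3)
        b = cm.simulate_autocorrelated_map(ico4, 20.0, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_independent_seeds_give_near_null_correlation(self, ico4):
        rs = []
        for seed in range(0, 120, 2):
            a = cm.simulate_autocorrelated_map(ico4, 20.0, seed=seed)
            b = cm.simulate_autocorrelated_map(ico4, 20.0, seed=seed + 1)
            rs.append(cm.spatial_pearson(a, b)[0])
        assert abs(np.mean(rs)) < 0.04
        assert np.mean(np.abs(rs)) < 0.25

    def test_smoothing_raises_neighbour_correlation(self, ico4):
        def lag1(vmap):
            e = ico4.edges
            return np.corrcoef(vmap.values[e[:, 0]], vmap.values[e[:, 1]])[0, 1]

        rough = cm.simulate_autocorrelated_map(ico4, 0.0, seed=9)
        smooth = cm.simulate_autocorrelated_map(ico4, 20.0, seed=9)
        assert lag1(smooth) > lag1(rough)

    def test_standardized_over_mask(self, ico4):
        vmap = cm.simulate_autocorrelated_map(ico4, 20.0, seed=4)
        assert abs(vmap.valid_values().mean()) < 1e-12
        assert np.isclose(vmap.valid_values().std(), 1.0, atol=1e-12)


class TestParcellation:
    def test_single_region_covers_cortex(self, ico3):
        labels = cm.simulate_parcellation(ico3, 1, seed=0)
        assert set(labels[ico3.cortex_mask]) == {0}

    def test_all_regions_present_and_connected(self, ico4):
        n_regions = 34
        labels = cm.simulate_parcellation(ico4, n_regions, seed=2)
        assert set(labels[ico4.cortex_mask]) == set(range(n_regions))
        adj = ico4.adjacency
        for region in range(n_regions):
            idx = np.flatnonzero(labels == region)
            n_comp, _ = connected_components(adj[idx][:, idx], directed=False)
            assert n_comp == 1

    def test_too_many_regions_rejected(self, ico3):
        with pytest.raises(ValueError):
            cm.simulate_parcellation(ico3, ico3.n_vertices + 1, seed=0)

    def test_noncortex_gets_reserved_label(self, ico3):
        mesh = cm.build_icosphere(3)
        mesh.cortex_mask[:50] = False
        labels = cm.simulate_parcellation(mesh, 5, seed=1)
        assert np.all(labels[:50] == -1)


class TestCohorts:
    def test_null_effect_gives_centred_beta_distribution(self, ico4):
        config = cm.CohortConfig(
            n_subjects=500, between_cohort_tau=0.0, site_effect=0.0,
            missingness_rate=0.0, noise_fwhm_mm=0.0, seed=13,
        )
        cohort = cm.simulate_cohort(ico4, config)
        res = cm.VertexWiseGLM(
            cohort.morphometry["volume"], cohort.truth["g"]
        ).fit()
        assert abs(res.beta_std.valid_values().mean()) < 0.01

    def test_constant_effect_recovered(self, flat_cohort):
        res = cm.VertexWiseGLM(
            flat_cohort.morphometry["volume"], flat_cohort.truth["g"]
        ).fit()
        assert abs(res.beta_std.valid_values().mean() - 0.15) < 0.02

    def test_test_score_covariance_matches_factor_model(self, ico3):
        config = cm.CohortConfig(
            n_subjects=5000, missingness_rate=0.0, seed=19,
            effect_map_g=None, noise_fwhm_mm=0.0, between_cohort_tau=0.0,
        )
        cohort = cm.simulate_cohort(ico3, config)
        observed = np.cov(cohort.test_scores.to_numpy().T, ddof=0)
        lam, psi = config.test_loadings, config.test_uniquenesses
        implied = np.outer(lam, lam) + np.diag(psi)
        assert np.max(np.abs(observed - implied)) < 0.05

    def test_missingness_flagged_not_zeroed(self, ico4):
        config = cm.CohortConfig(n_subjects=200, missingness_rate=0.3, seed=3)
        cohort = cm.simulate_cohort(ico4, config)
        frac = cohort.test_scores.isna().to_numpy().mean()
        assert 0.2 < frac < 0.4
        assert not (cohort.test_scores == 0).all().any()

    def test_generation_is_deterministic(self, ico3):
        config = cm.CohortConfig(n_subjects=50, seed=7)
        with pytest.raises(ValueError):
            cm.CohortConfig(n_subjects=5, seed=7)  # too few subjects
        a = cm.simulate_cohort(ico3, dataclasses.replace(config))
        b = cm.simulate_cohort(ico3, dataclasses.replace(config))
        assert np.array_equal(
            a.morphometry["volume"], b.morphometry["volume"], equal_nan=True
        )
        assert a.covariates.equals(b.covariates)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cm.CohortConfig(n_subjects=100, test_loadings=np.array([1.2, 0.5, 0.4]))
        with pytest.raises(ValueError):
            cm.CohortConfig(n_subjects=100, missingness_rate=1.0)


class TestMapStack:
    def test_rank_one_stack_fully_correlated(self, ico3):
        maps, _ = cm.simulate_map_stack(ico3, n_maps=5, n_latent=1, noise_sd=0.0, seed=1)
        for other in maps[1:]:
            r, _ = cm.spatial_pearson(maps[0], other)
            assert abs(abs(r) - 1.0) < 1e-9

    def test_four_latents_dominate_variance(self, ico4):
        maps, _ = cm.simulate_map_stack(
            ico4, n_maps=33, n_latent=4, noise_sd=0.2, seed=5
        )
        res = cm.MapPCA(cm.stack_maps(maps), 10).fit()
        pct = res.variance_explained_pct
        assert pct[:4].sum() > 60.0
        assert pct[:4].sum() > np.sort(pct[:10])[-5:-1].sum()  # beats any other 4-subset

    def test_recorded_latents_near_orthogonal(self, ico4):
        _, truth = cm.simulate_map_stack(ico4, n_maps=8, n_latent=4, seed=2)
        lm = truth["latents"][:, ico4.cortex_mask]
        corr = np.corrcoef(lm)
        off = np.abs(corr[np.triu_indices(4, 1)])
        assert off.max() < 0.1

    def test_latent_count_validated(self, ico3):
        with pytest.raises(ValueError):
            cm.simulate_map_stack(ico3, n_maps=3, n_latent=4, seed=0)
        with pytest.raises(ValueError):
            simple_structure_loadings(3, 4)


class TestAreaCohorts:
    def test_isometric_total_is_scaled_template(self, ico3):
        areas, totals = simulate_area_cohort(ico3, 20, noise_sd=0.0, seed=1)
        template = cm.vertex_areas(ico3).values
        ratio = areas / template[None, :]
        assert np.allclose(ratio, ratio[:, [0]], rtol=1e-12)
        assert np.allclose(totals, areas.sum(axis=1))
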