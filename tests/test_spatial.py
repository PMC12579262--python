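"""Spatial correlations, spin permutation inference, regional decomposition."""

import numpy as np
import pytest
from scipy import stats

import cortexmeta as cm
from cortexmeta.spatial import (
    _assignment_for_rotation,
    covariance_decomposition,
    spin_test,
    within_region_corr,
)
from cortexmeta.surface import VertexMap


def vmap(values, mask=None):
    values = np.asarray(values, dtype=float)
    return VertexMap(values, mask if mask is not None else np.isfinite(values))


class TestSpatialPearson:
    def test_self_and_negated(self, ico4):
        a = cm.simulate_autocorrelated_map(ico4, 20, seed=1)
        neg = vmap(-a.values, a.valid_mask.copy())
        assert np.isclose(cm.spatial_pearson(a, a)[0], 1.0)
        assert np.isclose(cm.spatial_pearson(a, neg)[0], -1.0)

    def test_four_vertex_hand_value(self):
        a = vmap([1.0, 2.0, 3.0, 4.0])
        b = vmap([2.0, 1.0, 4.0, 3.0])
        r, n = cm.spatial_pearson(a, b)
        assert np.isclose(r, 0.6)
        assert n == 4

    def test_affine_invariance(self, ico4):
        a = cm.simulate_autocorrelated_map(ico4, 20, seed=2)
        b = cm.simulate_autocorrelated_map(ico4, 20, seed=3)
        r0 = cm.spatial_pearson(a, b)[0]
        scaled = vmap(-2.0 * b.values + 5.0, b.valid_mask.copy())
        assert np.isclose(cm.spatial_pearson(a, scaled)[0], -r0, atol=1e-12)

    def test_mask_intersection_and_degenerate_errors(self):
        a = vmap([1.0, 2.0, np.nan, 4.0])
        b = vmap([np.nan, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cm.spatial_pearson(a, b)  # only 2 joint vertices
        const = vmap([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            cm.spatial_pearson(vmap([1.0, 2.0, 3.0, 4.0]), const)


class TestSpinEnsemble:
    def test_identity_rotation_maps_to_self(self, ico3):
        asg = _assignment_for_rotation(ico3, np.eye(3))
        assert np.array_equal(asg, np.arange(ico3.n_vertices))

    def test_rotations_are_isometries(self, spins200, ico4):
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, ico4.n_vertices, (100, 2))
        sphere = ico4.sphere_coords
        for rot in spins200.rotation_log[:10]:
            before = np.einsum("ij,ij->i", sphere[pairs[:, 0]], sphere[pairs[:, 1]])
            ra, rb = sphere[pairs[:, 0]] @ rot.T, sphere[pairs[:, 1]] @ rot.T
            after = np.einsum("ij,ij->i", ra, rb)
            assert np.max(np.abs(np.arccos(np.clip(before, -1, 1))
                                 - np.arccos(np.clip(after, -1, 1)))) < 1e-6

    def test_regeneration_reproduces_table(self, ico3):
        a = cm.generate_spins(ico3, 25, seed=5)
        b = cm.generate_spins(ico3, 25, seed=5)
        assert np.array_equal(a.vertex_assignment, b.vertex_assignment)

    def test_rotated_image_covers_sphere_uniformly(self, ico3):
        ens = cm.generate_spins(ico3, 2000, seed=8)
        v0 = ico3.sphere_coords[0]
        images = np.einsum("sij,j->si", ens.rotation_log, v0)
        octant = (
            (images[:, 0] > 0).astype(int) * 4
            + (images[:, 1] > 0).astype(int) * 2
            + (images[:, 2] > 0).astype(int)
        )
        counts = np.bincount(octant, minlength=8)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_mirrored_rotation_for_bilateral_meshes(self, ico3):
        mesh = cm.build_icosphere(3)
        hemi = np.where(mesh.sphere_coords[:, 0] < 0, "L", "R")
        mesh = cm.SurfaceMesh(
            mesh.vertex_coords, mesh.triangles, mesh.sphere_coords,
            mesh.cortex_mask, hemisphere=hemi,
        )
        ens = cm.generate_spins(mesh, 5, seed=1)
        for s in range(5):
            asg = ens.vertex_assignment[s]
            assert np.all(hemi[asg] == hemi)  # assignments stay within hemisphere


class TestSpinTest:
    def test_smallest_p_and_formula(self, ico4, spins200):
        a = cm.simulate_autocorrelated_map(ico4, 20, seed=30)
        self_test = spin_test(a, a, spins200)
        assert self_test.r == 1.0
        assert self_test.p_spin >= 1.0 / (spins200.n_spins + 1)
        assert self_test.p_spin == (1 + np.sum(
            np.abs(self_test.null_r[np.isfinite(self_test.null_r)]) >= 1.0
        )) / (1 + spins200.n_spins)

    def test_short_ensemble_warns(self, ico3):
        ens = cm.generate_spins(ico3, 50, seed=2)
        a = cm.simulate_autocorrelated_map(ico3, 20, seed=31)
        b = cm.simulate_autocorrelated_map(ico3, 20, seed=32)
        with pytest.warns(UserWarning):
            spin_test(a, b, ens)

    def test_spin_choice_symmetric_in_expectation(self, ico4, spins200):
        diffs = []
        for seed in range(40):
            a = cm.simulate_autocorrelated_map(ico4, 20, seed=4000 + seed)
            b = cm.simulate_autocorrelated_map(ico4, 20, seed=8000 + seed)
            pa = spin_test(a, b, spins200, spin_which="A").p_spin
            pb = spin_test(a, b, spins200, spin_which="B").p_spin
            diffs.append(abs(pa - pb))
        assert np.mean(diffs) < 0.05

    def test_masked_sources_dropped_pairwise(self, ico4, spins200):
        a = cm.simulate_autocorrelated_map(ico4, 20, seed=40)
        masked_vals = a.values.copy()
        masked_vals[:300] = np.nan
        a_masked = VertexMap(masked_vals, np.isfinite(masked_vals))
        b = cm.simulate_autocorrelated_map(ico4, 20, seed=41)
        res = spin_test(a_masked, b, spins200)
        assert res.n_vertices_used == ico4.n_vertices - 300
        assert np.all(np.isfinite(res.null_r))


class TestWithinRegion:
    def test_single_region_equals_global(self, ico4):
        a = cm.simulate_autocorrelated_map(ico4, 20, seed=50)
        b = cm.simulate_autocorrelated_map(ico4, 20, seed=51)
        labels = np.zeros(ico4.n_vertices, dtype=int)
        table, _ = within_region_corr(a, b, labels, min_vertices=10)
        assert np.isclose(table["r"].iloc[0], cm.spatial_pearson(a, b)[0])

    def test_simpsons_paradox_construction(self):
        # two clusters offset along the identity line; within-slopes negative
        t = np.linspace(-1, 1, 50)
        a = np.concatenate([t, t + 5.0])
        b = np.concatenate([-0.8 * t, -0.8 * t + 5.0])
        labels = np.repeat([0, 1], 50)
        table, summary = within_region_corr(vmap(a), vmap(b), labels, min_vertices=10)
        assert np.all(table["r"] < 0)
        global_r = np.corrcoef(a, b)[0, 1]
        assert global_r > 0
        assert summary["n_negative"] == 2

    def test_small_region_reported_missing(self):
        a = vmap(np.arange(30, dtype=float))
        b = vmap(np.arange(30, dtype=float)[::-1].copy())
        labels = np.zeros(30, dtype=int)
        labels[:2] = 1
        table, summary = within_region_corr(a, b, labels, min_vertices=10)
        small = table[table["region"] == 1]
        assert np.isnan(small["r"].iloc[0])
        assert summary["n_missing"] == 1

    def test_no_region_large_enough_errors(self):
        a = vmap(np.arange(6, dtype=float))
        b = vmap(np.arange(6, dtype=float))
        with pytest.raises(ValueError):
            within_region_corr(a, b, np.arange(6) // 2, min_vertices=10)


class TestCovarianceDecomposition:
    def test_identity_on_random_maps_and_parcellations(self, ico4):
        rng = np.random.default_rng(3)
        for trial in range(10):
            a = cm.simulate_autocorrelated_map(ico4, 15, seed=600 + trial)
            b = cm.simulate_autocorrelated_map(ico4, 15, seed=700 + trial)
            labels = cm.simulate_parcellation(ico4, int(rng.integers(2, 40)), seed=trial)
            out = covariance_decomposition(a, b, labels)
            assert abs(out["total"] - (out["within"] + out["between"])) < 1e-10
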