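"""Random-effects meta-analysis, moderator meta-regression and BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import cortexmeta as cm
from cortexmeta.meta import (
    MetaRegression,
    RandomEffectsMeta,
    fdr_bh,
    meta_moderator,
    meta_random_effects,
)


class TestRandomEffects:
    def test_zero_heterogeneity_identical_betas(self):
        beta, se, p, tau2, q = meta_random_effects([0.2, 0.2, 0.2], [0.1, 0.05, 0.2])
        assert np.isclose(beta, 0.2)
        assert tau2 == 0.0
        assert np.isclose(q, 0.0)

    def test_dersimonian_laird_hand_example(self):
        beta, se, p, tau2, q = meta_random_effects([0.2, 0.4], [0.1, 0.1], method="DL")
        assert abs(beta - 0.3) < 1e-10
        assert abs(tau2 - 0.01) < 1e-10
        assert abs(se - 0.1) < 1e-10
        assert abs(q - 2.0) < 1e-10

    def test_equal_se_zero_tau_gives_arithmetic_mean(self):
        betas = np.array([0.05, 0.06, 0.055])  # Q < k-1 so tau2 truncates to 0
        beta, se, p, tau2, q = meta_random_effects(betas, [0.1, 0.1, 0.1])
        assert tau2 == 0.0
        assert np.isclose(beta, betas.mean())

    def test_dl_and_reml_agree_when_truncated(self):
        # equal SEs: both estimators truncate at zero exactly when Q <= k-1
        rng = np.random.default_rng(4)
        for _ in range(50):
            betas = rng.normal(0, 0.01, 4)
            ses = np.full(4, 0.2)
            _, _, _, t_dl, q = meta_random_effects(betas, ses, method="DL")
            _, _, _, t_reml, _ = meta_random_effects(betas, ses, method="REML")
            if q <= 3:
                assert t_dl == 0.0 and t_reml == 0.0

    def test_pooled_beta_is_convex_combination(self):
        rng = np.random.default_rng(9)
        betas = rng.normal(0, 0.2, (5, 200))
        ses = rng.uniform(0.02, 0.3, (5, 200))
        res = RandomEffectsMeta(betas, ses).fit()
        assert np.all(res.beta >= betas.min(axis=0) - 1e-12)
        assert np.all(res.beta <= betas.max(axis=0) + 1e-12)

    def test_vectorised_equals_looped_bitwise(self):
        rng = np.random.default_rng(2)
        betas = rng.normal(0, 0.1, (3, 50))
        ses = rng.uniform(0.01, 0.1, (3, 50))
        vec = RandomEffectsMeta(betas, ses, method="DL").fit()
        for v in range(50):
            res = RandomEffectsMeta(betas[:, v], ses[:, v], method="DL").fit()
            assert res.beta[0] == vec.beta[v]
            assert res.tau2[0] == vec.tau2[v]

    def test_fe_equals_re_where_tau_zero(self):
        rng = np.random.default_rng(3)
        betas = rng.normal(0.1, 0.001, (3, 100))
        ses = rng.uniform(0.05, 0.1, (3, 100))
        re = RandomEffectsMeta(betas, ses, method="DL").fit()
        fe = RandomEffectsMeta(betas, ses, method="FE").fit()
        zero = re.tau2 == 0
        assert zero.any()
        assert np.allclose(re.beta[zero], fe.beta[zero])

    def test_recovery_under_simulated_heterogeneity(self):
        rng = np.random.default_rng(7)
        nv, k = 1000, 3
        true = 0.1
        tau = 0.05
        ses = np.full((k, nv), 0.02)
        betas = true + rng.normal(0, tau, (k, nv)) + rng.normal(0, 0.02, (k, nv))
        res = RandomEffectsMeta(betas, ses).fit()
        assert abs(res.beta.mean() - true) < 0.01
        assert abs(res.tau2.mean() - tau**2) < 0.5 * tau**2

    def test_missing_cohorts_pooled_on_available_k(self):
        rng = np.random.default_rng(21)
        betas = rng.normal(0.1, 0.05, (3, 20))
        ses = rng.uniform(0.02, 0.1, (3, 20))
        betas[0, 5] = np.nan      # one cohort missing: pool the other two
        betas[:2, 9] = np.nan     # only one cohort left: vertex invalid
        res = RandomEffectsMeta(betas, ses, method="DL").fit()
        assert np.isnan(res.beta[9]) and np.isnan(res.tau2[9])
        two = RandomEffectsMeta(betas[1:, 5], ses[1:, 5], method="DL").fit()
        assert np.isclose(res.beta[5], two.beta[0])
        assert res.k_per_vertex[5] == 2 and res.k_per_vertex[9] == 1
        full = RandomEffectsMeta(
            np.delete(betas, [5, 9], axis=1), np.delete(ses, [5, 9], axis=1),
            method="DL",
        ).fit()
        assert np.allclose(np.delete(res.beta, [5, 9]), full.beta)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            RandomEffectsMeta([0.1], [0.1])
        with pytest.raises(ValueError):
            RandomEffectsMeta([0.1, 0.2], [0.1, 0.0])

    def test_knapp_hartung_widens_small_k_intervals(self):
        rng = np.random.default_rng(11)
        betas = rng.normal(0.1, 0.1, 3)
        ses = np.full(3, 0.05)
        wald = RandomEffectsMeta(betas, ses).fit()
        kh = RandomEffectsMeta(betas, ses, knapp_hartung=True).fit()
        assert kh.p[0] >= wald.p[0]

    def test_reml_matches_direct_likelihood_maximisation(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            k = 3
            ses = rng.uniform(0.02, 0.2, k)
            betas = rng.normal(0.1, 0.15, k)
            _, _, _, tau2, _ = meta_random_effects(betas, ses, method="REML")

            def neg_restricted_ll(t):
                w = 1.0 / (ses**2 + t)
                mu = (w * betas).sum() / w.sum()
                return 0.5 * (
                    np.sum(np.log(ses**2 + t))
                    + np.log(w.sum())
                    + np.sum(w * (betas - mu) ** 2)
                )

            brute = optimize.minimize_scalar(
                neg_restricted_ll, bounds=(0.0, 5.0), method="bounded",
                options={"xatol": 1e-13},
            )
            assert (
                abs(tau2 - max(brute.x, 0.0)) < 1e-6
                or neg_restricted_ll(tau2) <= neg_restricted_ll(brute.x) + 1e-12
            )


class TestMetaRegression:
    def test_exact_linear_relation_recovered(self):
        mod = np.array([50.0, 60.0, 70.0, 80.0])
        betas = 0.5 - 0.004 * mod
        slope, se, p = meta_moderator(betas, np.full(4, 0.05), mod)
        assert abs(slope + 0.004) < 1e-8
        res = MetaRegression(betas, np.full(4, 0.05), mod).fit()
        assert res.q_resid[0] < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            meta_moderator([0.1, 0.2], [0.1, 0.1], [1.0, 2.0])  # k = 2
        with pytest.raises(ValueError):
            meta_moderator([0.1, 0.2, 0.3], [0.1] * 3, [1.0, 1.0, 1.0])  # constant

    def test_null_moderation_type_i_error(self):
        rng = np.random.default_rng(23)
        k, nv = 8, 2000
        mod = rng.normal(60, 8, k)
        ses = np.full((k, nv), 0.03)
        betas = 0.1 + rng.normal(0, 0.03, (k, nv))
        res = MetaRegression(betas, ses, mod).fit()
        rate = float((res.p < 0.05).mean())
        assert 0.03 <= rate <= 0.08


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert fdr_bh(np.array([0.03]))[0] == 0.03

    def test_hand_example(self):
        q = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40).map(np.array)
    )
    def test_order_preserving_and_bounded(self, p):
        q = fdr_bh(p)
        assert np.all((q >= 0) & (q <= 1))
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)
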