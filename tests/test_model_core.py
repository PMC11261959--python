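"""Moment algebra of the twin path models: causal matrices, expected pair
moments, Cholesky ACE moments and parameter-count arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mixdoc as mx
from mixdoc.model_core import (
    BIDIRECTIONAL_LABEL,
    Direction,
    family_class_labels,
    psi_matrix,
)

XY, YX = Direction.XY, Direction.YX
CONC_XY, CONC_YX, DISC_A, DISC_B = mx.MIXTURE_LABELS


def random_params(rng, confounded=True) -> mx.DoCParams:
    r = (lambda: rng.uniform(-0.85, 0.85)) if confounded else (lambda: 0.0)
    return mx.DoCParams(
        a_x=rng.uniform(0.1, 1.0), c_x=rng.uniform(0.1, 1.0), e_x=rng.uniform(0.3, 1.0),
        a_y=rng.uniform(0.1, 1.0), c_y=rng.uniform(0.1, 1.0), e_y=rng.uniform(0.3, 1.0),
        b_xy=rng.uniform(-0.8, 0.8), b_yx=rng.uniform(-0.8, 0.8),
        nu_x_xy=rng.normal(), nu_y_xy=rng.normal(),
        nu_x_yx=rng.normal(), nu_y_yx=rng.normal(),
        r_a=r(), r_c=r(), r_e=r(),
    )


class TestCausalMatrix:
    def test_concordant_xy_places_single_regression_per_twin(self):
        B = mx.causal_matrix(CONC_XY, b_xy=0.5, b_yx=0.3)
        expected = np.zeros((4, 4))
        expected[1, 0] = expected[3, 2] = 0.5  # y <- x in both twins
        np.testing.assert_array_equal(B, expected)

    def test_zero_effects_give_identity_reduced_form(self):
        B = mx.causal_matrix(CONC_XY, 0.0, 0.0)
        np.testing.assert_array_equal(B, np.zeros((4, 4)))
        np.testing.assert_array_equal(np.linalg.inv(np.eye(4) - B), np.eye(4))

    def test_discordant_label_mixes_directions_across_twins(self):
        B = mx.causal_matrix(DISC_A, b_xy=0.5, b_yx=0.3)
        expected = np.zeros((4, 4))
        expected[1, 0] = 0.5  # twin 1: y <- x
        expected[2, 3] = 0.3  # twin 2: x <- y
        np.testing.assert_array_equal(B, expected)

    def test_reciprocal_unit_product_is_singular(self):
        with pytest.raises(ValueError, match="singular"):
            mx.causal_matrix(BIDIRECTIONAL_LABEL, b_xy=2.0, b_yx=0.5)


class TestExpectedPairMoments:
    def test_no_connecting_path_zeroes_cross_trait_covariances(self):
        p = mx.DoCParams(a_x=0.8, c_x=0.4, e_x=0.5, a_y=0.3, c_y=0.7, e_y=0.6,
                         b_xy=0.0, b_yx=0.0)
        pm = mx.expected_pair_moments(p, CONC_XY, "MZ")
        for i, j in [(0, 1), (0, 3), (2, 1), (2, 3)]:
            assert pm.sigma[i, j] == pytest.approx(0.0, abs=1e-14)
        assert pm.sigma[0, 2] == pytest.approx(p.a_x**2 + p.c_x**2)

    def test_cross_twin_cross_trait_signature(self, rng):
        # the DoC fingerprint: cov(x1, y2) = b_xy * cov(x1, x2) without confounding
        for _ in range(5):
            p = random_params(rng, confounded=False)
            for zyg in ("MZ", "DZ"):
                pm = mx.expected_pair_moments(p, CONC_XY, zyg)
                assert pm.sigma[0, 3] == pytest.approx(p.b_xy * pm.sigma[0, 2], rel=1e-10)

    def test_signature_confirmed_by_structural_monte_carlo(self):
        p = mx.make_params(b_xy=0.8, b_yx=0.3, mean_diff_x=0.0, mean_diff_y=0.0)
        cfg = mx.ScenarioConfig(n_mz=10**6, n_dz=0, params=p, family="doc_xy", seed=5)
        emp = np.cov(mx.structural_simulate(cfg).by_zygosity("MZ").T)
        assert emp[0, 3] / emp[0, 2] == pytest.approx(0.8, abs=0.01)

    def test_moments_match_structural_simulation_at_large_n(self, rng):
        p = random_params(np.random.default_rng(3))
        cfg = mx.ScenarioConfig(
            n_mz=5 * 10**5, n_dz=5 * 10**5, params=p, family="mix4", seed=9,
            fixed_quota=True, weights=mx.MixtureWeights((1.0, 0.0, 0.0, 0.0),
                                                        (0.0, 1.0, 0.0, 0.0)),
        )
        data = mx.structural_simulate(cfg)
        for zyg, label in (("MZ", CONC_XY), ("DZ", CONC_YX)):
            Y = data.by_zygosity(zyg)
            pm = mx.expected_pair_moments(p, label, zyg)
            np.testing.assert_allclose(Y.mean(axis=0), pm.mu, atol=0.01)
            np.testing.assert_allclose(np.cov(Y.T), pm.sigma, atol=0.012)

    @given(seed=st.integers(0, 10**6))
    def test_sigma_symmetric_positive_definite_everywhere(self, seed):
        p = random_params(np.random.default_rng(seed))
        for label in (*mx.MIXTURE_LABELS, BIDIRECTIONAL_LABEL):
            for zyg in ("MZ", "DZ"):
                pm = mx.expected_pair_moments(p, label, zyg)
                np.testing.assert_allclose(pm.sigma, pm.sigma.T, atol=1e-12)
                assert np.linalg.eigvalsh(pm.sigma)[0] > 0

    def test_zygosity_groups_differ_only_through_genetic_paths(self, rng):
        p = random_params(rng).replace(a_x=0.0, a_y=0.0, r_a=0.0)
        for label in mx.MIXTURE_LABELS:
            mz = mx.expected_pair_moments(p, label, "MZ")
            dz = mx.expected_pair_moments(p, label, "DZ")
            np.testing.assert_allclose(mz.sigma, dz.sigma, atol=1e-12)
            np.testing.assert_allclose(mz.mu, dz.mu, atol=1e-12)

    def test_twin_swap_maps_one_discordant_class_onto_the_other(self, rng):
        p = random_params(rng)
        perm = [2, 3, 0, 1]
        for zyg in ("MZ", "DZ"):
            a = mx.expected_pair_moments(p, DISC_A, zyg)
            b = mx.expected_pair_moments(p, DISC_B, zyg)
            np.testing.assert_allclose(a.sigma[np.ix_(perm, perm)], b.sigma, atol=1e-12)
            np.testing.assert_allclose(a.mu[perm], b.mu, atol=1e-12)

    def test_improper_density_rejected_with_class_context(self):
        p = mx.DoCParams(a_x=0.0, c_x=0.0, e_x=0.0, a_y=0.5, c_y=0.5, e_y=0.5)
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            mx.expected_pair_moments(p, CONC_XY, "MZ")


class TestCholeskyMoments:
    def test_diagonal_factors_reduce_to_independent_univariate_ace(self):
        chol = mx.CholeskyParams(
            l_a=np.diag([0.8, 0.3]), l_c=np.diag([0.4, 0.7]),
            l_e=np.diag([0.5, 0.6]), mu=np.zeros(2),
        )
        pm = mx.cholesky_ace_moments(chol, "DZ")
        assert pm.sigma[0, 1] == 0 and pm.sigma[0, 3] == 0
        assert pm.sigma[0, 2] == pytest.approx(0.5 * 0.8**2 + 0.4**2)
        assert pm.sigma[1, 3] == pytest.approx(0.5 * 0.3**2 + 0.7**2)

    def test_no_familial_variance_makes_zygosities_identical(self):
        chol = mx.CholeskyParams(
            l_a=np.zeros((2, 2)), l_c=np.zeros((2, 2)),
            l_e=np.array([[0.9, 0.0], [0.2, 0.7]]), mu=np.array([1.0, -1.0]),
        )
        mz = mx.cholesky_ace_moments(chol, "MZ")
        dz = mx.cholesky_ace_moments(chol, "DZ")
        np.testing.assert_allclose(mz.sigma, dz.sigma)
        assert mz.sigma[0, 2] == 0  # E never crosses twins

    def test_generic_factors_match_monte_carlo(self):
        chol = mx.CholeskyParams(
            l_a=np.array([[0.8, 0.0], [0.3, 0.4]]),
            l_c=np.array([[0.4, 0.0], [0.1, 0.6]]),
            l_e=np.array([[0.5, 0.0], [0.2, 0.5]]), mu=np.array([0.3, -0.2]),
        )
        rng = np.random.default_rng(17)
        n = 4 * 10**5
        for zyg, gamma in (("MZ", 1.0), ("DZ", 0.5)):
            pm = mx.cholesky_ace_moments(chol, zyg)
            # direct latent-variable simulation of the factor model
            s, q = np.sqrt(gamma), np.sqrt(1 - gamma)
            A = s * rng.standard_normal((n, 2))[:, None, :] + q * rng.standard_normal((n, 2, 2))
            C = np.repeat(rng.standard_normal((n, 1, 2)), 2, axis=1)
            E = rng.standard_normal((n, 2, 2))
            y = A @ chol.l_a.T + C @ chol.l_c.T + E @ chol.l_e.T + chol.mu
            flat = y.reshape(n, 4)
            np.testing.assert_allclose(np.cov(flat.T), pm.sigma, atol=0.012)

    def test_unidirectional_doc_is_nested_in_cholesky(self, rng):
        # exact reconstruction: residual far below 1e-8 on random instances
        for _ in range(5):
            p = random_params(rng, confounded=False)
            T = np.linalg.inv(np.eye(2) - np.array([[0.0, 0.0], [p.b_xy, 0.0]]))
            mk = lambda lx, ly: np.linalg.cholesky(
                T @ np.diag([lx**2, ly**2]) @ T.T + 1e-15 * np.eye(2)
            )
            chol = mx.CholeskyParams(
                l_a=mk(p.a_x, p.a_y), l_c=mk(p.c_x, p.c_y), l_e=mk(p.e_x, p.e_y),
                mu=T @ np.array([p.nu_x_xy, p.nu_y_xy]),
            )
            for zyg in ("MZ", "DZ"):
                doc = mx.expected_pair_moments(p, CONC_XY, zyg)
                ace = mx.cholesky_ace_moments(chol, zyg)
                assert np.abs(doc.sigma - ace.sigma).max() < 1e-8
                assert np.abs(doc.mu - ace.mu).max() < 1e-8


class TestParameterCounting:
    @pytest.mark.parametrize(
        "family,expected",
        [("mix4", 16), ("mix2", 14), ("doc_xy", 9), ("doc_yx", 9),
         ("doc_bidir", 10), ("cholesky", 11)],
    )
    def test_free_parameter_counts(self, family, expected):
        assert mx.count_free_parameters(mx.ModelSpec(family)) == expected

    def test_freeing_genetic_confounding_adds_one(self):
        base = mx.count_free_parameters(mx.ModelSpec("doc_xy"))
        extended = mx.count_free_parameters(mx.ModelSpec("doc_xy", confound_ra_free=True))
        assert extended == base + 1

    def test_pooled_proportions_drop_one_per_group(self):
        assert mx.count_free_parameters(
            mx.ModelSpec("mix4", proportions_by_zygosity=False)
        ) == 14

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            mx.count_free_parameters(mx.ModelSpec("mix3"))

    def test_df_is_datapoints_minus_parameters(self):
        assert mx.model_df(mx.ModelSpec("mix4"), 30000 * 4) == 119984
        assert mx.model_df(mx.ModelSpec("doc_bidir"), 10000 * 4) == 39990

    def test_overparameterized_model_rejected(self):
        with pytest.raises(ValueError, match="over-parameterized"):
            mx.model_df(mx.ModelSpec("mix2"), 0)


def test_family_class_labels_enumerate_the_four_direction_combinations():
    labels = family_class_labels("mix4")
    assert len(set(labels)) == 4
    assert sum(l.twin1 == l.twin2 for l in labels) == 2  # two concordant
    assert family_class_labels("mix2") == labels[:2]
    assert family_class_labels("doc_bidir") == (BIDIRECTIONAL_LABEL,)


def test_psi_cross_twin_blocks_follow_component_correlations():
    p = mx.DoCParams(a_x=0.6, c_x=0.5, e_x=0.4, a_y=0.3, c_y=0.7, e_y=0.5,
                     r_a=0.4, r_c=0.2, r_e=0.1)
    psi_mz, psi_dz = psi_matrix(p, "MZ"), psi_matrix(p, "DZ")
    assert psi_mz[0, 2] == pytest.approx(p.a_x**2 + p.c_x**2)
    assert psi_dz[0, 2] == pytest.approx(0.5 * p.a_x**2 + p.c_x**2)
    # within-twin vs cross-twin cross-trait entries differ by the E term only (MZ)
    assert psi_mz[0, 1] - psi_mz[0, 3] == pytest.approx(p.r_e * p.e_x * p.e_y)
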