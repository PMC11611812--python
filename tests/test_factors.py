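"""Factor pipeline: adequacy statistics, extraction, rotation, scoring.

The principal-axis eigen-step is cross-checked against a brute-force
least-squares discrepancy minimizer for small p, and the whole pipeline
against data simulated from known loading structures.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pupilspan.factors import (bartlett_sphericity, choose_n_factors,
                               correlation_matrix, factor_factor_correlation,
                               factor_scores, fit_factor_model, kmo,
                               match_factors, oblimin_rotate,
                               principal_axis_factoring,
                               significant_loadings, tucker_congruence)
from pupilspan.synthetic import generate_measure_rows

ONE_FACTOR_LOADINGS = np.array([0.8, 0.7, 0.6])
R1 = np.outer(ONE_FACTOR_LOADINGS, ONE_FACTOR_LOADINGS) + \
    np.diag(1.0 - ONE_FACTOR_LOADINGS ** 2)


class TestCorrelationMatrix:
    def test_duplicated_column_rho_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        R = correlation_matrix(df, method="spearman")
        assert R.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 4)),
                          columns=list("abcd"))
        R = correlation_matrix(df, method="spearman").to_numpy()
        assert np.abs(R[~np.eye(4, dtype=bool)]).max() < 0.1

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=80),
                           "b": rng.normal(size=80)})
        R1s = correlation_matrix(df, method="spearman")
        df2 = df.copy()
        df2["a"] = np.exp(df2["a"])
        R2s = correlation_matrix(df2, method="spearman")
        assert R1s.loc["a", "b"] == pytest.approx(R2s.loc["a", "b"])

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"a": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)


class TestKmo:
    def test_two_variables_exactly_half(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        overall, per_var = kmo(R)
        assert overall == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(per_var, 0.5)

    def test_block_factor_structure_adequate(self):
        lam = np.zeros((9, 3))
        for j in range(3):
            lam[3 * j:3 * j + 3, j] = 0.8
        R = lam @ lam.T + np.diag(1.0 - np.sum(lam ** 2, axis=1))
        overall, per_var = kmo(R)
        assert overall > 0.6
        assert (per_var > 0.5).all()

    def test_near_identity_inadequate(self):
        rng = np.random.default_rng(0)
        E = rng.normal(0, 0.02, (6, 6))
        R = np.eye(6) + (E + E.T) / 2
        np.fill_diagonal(R, 1.0)
        overall, _ = kmo(R)
        assert overall < 0.5


class TestBartlett:
    def test_identity_chi2_zero(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_is_91_for_14_variables(self):
        _, df, _ = bartlett_sphericity(np.eye(14) , n=100)
        assert df == 91

    def test_hand_computed_three_variables(self):
        R = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        n = 50
        chi2, df, _ = bartlett_sphericity(R, n)
        expected = -(n - 1 - (2 * 3 + 5) / 6.0) * np.log(np.linalg.det(R))
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert df == 3


class TestPaf:
    def test_one_factor_matrix_recovered(self):
        loadings, h2 = principal_axis_factoring(R1, 1)
        np.testing.assert_allclose(loadings[:, 0], ONE_FACTOR_LOADINGS,
                                   atol=1e-3)

    def test_identity_matrix_no_common_variance(self):
        loadings, _ = principal_axis_factoring(np.eye(6), 1)
        assert np.abs(loadings).max() < 0.05

    def test_kaiser_counts(self):
        assert choose_n_factors(np.eye(6)) == 0   # strict > 1
        assert choose_n_factors(R1) == 1

    def test_brute_force_oracle_small_p(self):
        """PAF communalities match direct least-squares discrepancy fit."""
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        R = np.outer(lam, lam) + np.diag(1.0 - lam ** 2)
        loadings, h2 = principal_axis_factoring(R, 1, tol=1e-8)

        def discrepancy(h):
            red = R.copy()
            np.fill_diagonal(red, h)
            w, V = np.linalg.eigh(red)
            l1 = V[:, -1] * np.sqrt(max(w[-1], 0.0))
            fit = np.outer(l1, l1)
            np.fill_diagonal(fit, h)
            red2 = R.copy()
            np.fill_diagonal(red2, h)
            return np.sum((red2 - fit) ** 2)

        res = optimize.minimize(discrepancy, np.full(4, 0.5),
                                bounds=[(0.0, 0.999)] * 4)
        np.testing.assert_allclose(h2, res.x, atol=1e-3)


class TestOblimin:
    def test_single_factor_identity(self):
        L = np.array([[0.8], [0.7]])
        P, phi = oblimin_rotate(L)
        np.testing.assert_allclose(P, L)
        np.testing.assert_allclose(phi, [[1.0]])

    def test_communalities_preserved(self):
        table, _ = generate_measure_rows(300, seed=1)
        R = correlation_matrix(table)
        loadings, _ = principal_axis_factoring(R.to_numpy(), 3)
        P, phi = oblimin_rotate(loadings)
        h_before = np.sum(loadings ** 2, axis=1)
        h_after = np.diag(P @ phi @ P.T)
        np.testing.assert_allclose(h_before, h_after, atol=1e-8)

    def test_orthogonal_simple_structure_kept(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = 0.8
        lam[4:, 1] = 0.8
        R = lam @ lam.T + np.diag(1.0 - np.sum(lam ** 2, axis=1))
        loadings, _ = principal_axis_factoring(R, 2)
        P, phi = oblimin_rotate(loadings)
        _, cong, _ = match_factors(P, lam)
        assert min(cong) > 0.99
        assert abs(phi[0, 1]) < 0.05


class TestScoresAndMasks:
    def test_loading_threshold_strict(self):
        pattern = np.array([[0.30], [-0.31], [0.0]])
        mask = significant_loadings(pattern)
        assert mask.tolist() == [[False], [True], [False]]

    def test_scores_zero_mean_and_default_structure_recovery(self):
        from pupilspan.synthetic import DEFAULT_PUPIL_LOADINGS
        table, latents = generate_measure_rows(500, seed=3)
        model = fit_factor_model(table)
        assert model.n_factors == 3
        np.testing.assert_allclose(model.scores.mean().to_numpy(), 0.0,
                                   atol=1e-10)
        _, cong, _ = match_factors(model.pattern_loadings,
                                   DEFAULT_PUPIL_LOADINGS)
        assert min(cong) > 0.9

    def test_scores_track_latents_with_well_determined_factors(self):
        # >= 4 strong indicators per factor give score determinacy > 0.9
        L = np.zeros((14, 3))
        L[0:5, 0] = 0.8
        L[5:10, 1] = 0.8
        L[10:14, 2] = 0.8
        table, latents = generate_measure_rows(500, loading_matrix=L, seed=3)
        model = fit_factor_model(table)
        assert model.n_factors == 3
        perm, cong, _ = match_factors(model.pattern_loadings, L)
        assert min(cong) > 0.9
        for j, i in enumerate(perm):
            r = np.corrcoef(model.scores.iloc[:, i],
                            latents.iloc[:, j])[0, 1]
            assert abs(r) > 0.9

    def test_model_reconstructs_noiseless_correlation(self):
        from pupilspan.synthetic import DEFAULT_PUPIL_LOADINGS as L
        R = L @ L.T + np.diag(1.0 - np.sum(L ** 2, axis=1))
        loadings, h2 = principal_axis_factoring(R, 3, tol=1e-7)
        P, phi = oblimin_rotate(loadings)
        recon = P @ phi @ P.T + np.diag(1.0 - h2)
        assert np.abs(recon - R).max() < 1e-3


class TestFactorFactorCorrelation:
    def test_duplicated_factor_detected(self):
        rng = np.random.default_rng(0)
        p = pd.DataFrame(rng.normal(size=(100, 3)),
                         columns=["f1", "f2", "f3"])
        s = pd.DataFrame(rng.normal(size=(100, 4)),
                         columns=["g1", "g2", "g3", "g4"])
        s["g2"] = p["f1"]
        res = factor_factor_correlation(p, s)
        assert res.rho.loc["f1_pupil", "g2_saccade"] == pytest.approx(1.0)
        assert res.significant.loc["f1_pupil", "g2_saccade"]
        assert res.n_tests == 12

    def test_too_few_cases_rejected(self):
        p = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="at least 10"):
            factor_factor_correlation(p, p)


class TestTuckerCongruence:
    def test_self_congruence_one(self):
        v = np.array([0.8, -0.3, 0.1])
        assert tucker_congruence(v, v) == pytest.approx(1.0)
        assert tucker_congruence(v, -v) == pytest.approx(-1.0)
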