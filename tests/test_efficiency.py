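import numpy as np
import pytest

from jointeff import (
    CovarianceComponents,
    EfficiencyStudy,
    MarkerDesign,
    SubjectDesign,
    blup_map,
    fixed_effects_mse,
    gls_map,
    mse_ratio,
    predicted_values_mse,
    random_effects_mse,
    separate_components,
)

from conftest import bivariate_components, make_bivariate_subject


def make_sur_subjects(rng, n_subjects=3, n_obs=6):
    """Two-measure subjects with identical X across measures *and subjects*
    and Z a shared sub-matrix of X: the exact full-efficiency conditions
    for the separated fixed-effects estimator."""
    t = np.sort(rng.uniform(-1, 1, n_obs))
    X = np.column_stack([np.ones(n_obs), t, t**2])
    Z = X[:, :2]
    subjects = []
    for i in range(n_subjects):
        markers = tuple(
            MarkerDesign(f"m{k}", t, X.copy(), Z.copy()) for k in range(2)
        )
        subjects.append(SubjectDesign(f"s{i}", markers))
    return subjects


class TestScalarShrinkage:
    def test_half_shrinkage_decomposition(self, scalar_case):
        subject, comps = scalar_case
        dec = random_effects_mse(subject, comps, comps, beta_known=True)
        assert dec.mse == pytest.approx(0.5)
        assert dec.squared_bias == pytest.approx(0.25)
        assert dec.variance == pytest.approx(0.25)
        np.testing.assert_allclose(blup_map(subject, comps), [[0.5]])

    def test_zero_working_D_total_shrinkage(self, scalar_case):
        subject, comps = scalar_case
        zero = CovarianceComponents(np.zeros((1, 1)), comps.R, (1,))
        np.testing.assert_array_equal(blup_map(subject, zero), [[0.0]])
        dec = random_effects_mse(subject, zero, comps, beta_known=True)
        # b_hat = 0, so the MSE is E[b^2] = 1, all bias
        assert dec.mse == pytest.approx(1.0)
        assert dec.squared_bias == pytest.approx(1.0)


class TestGLSMap:
    def test_identity_weights_reduce_to_ols(self, rng):
        s = make_sur_subjects(rng, n_subjects=1)[0]
        comps = CovarianceComponents(np.zeros((4, 4)), np.eye(2), (2, 2))
        gmap = gls_map([s], comps)
        from jointeff import assemble_block_design

        X, _ = assemble_block_design(s)
        ols = np.linalg.solve(X.T @ X, X.T)
        np.testing.assert_allclose(gmap.A[0], ols, atol=1e-10)

    def test_unbiasedness_identity(self, rng, bivariate_cell):
        subject, true_c, sep = bivariate_cell
        from jointeff import assemble_block_design

        for w in (true_c, sep):
            gmap = gls_map([subject], w)
            X, _ = assemble_block_design(subject)
            np.testing.assert_allclose(gmap.A[0] @ X, np.eye(4), atol=1e-8)

    def test_separated_map_block_diagonal(self, rng):
        subjects = make_sur_subjects(rng)
        sep = separate_components(bivariate_components("A", 0.8, 0.6))
        gmap = gls_map(subjects, sep)
        for A in gmap.A:
            # coefficient rows of measure 1 use only measure-1 observations
            n1 = subjects[0].markers[0].n_obs
            assert np.abs(A[:3, n1:]).max() < 1e-12
            assert np.abs(A[3:, :n1]).max() < 1e-12

    def test_dense_normal_equation_oracle(self, rng):
        subjects = make_sur_subjects(rng)
        comps = bivariate_components("B", 0.6, 0.4, 0.2)
        from jointeff import assemble_block_design, marginal_cov

        gmap = gls_map(subjects, comps)
        # brute-force GLS on the stacked study
        XtWX = np.zeros((6, 6))
        maps = []
        for s in subjects:
            X, _ = assemble_block_design(s)
            W = np.linalg.inv(marginal_cov(s, comps))
            XtWX += X.T @ W @ X
            maps.append((X, W))
        for A, (X, W) in zip(gmap.A, maps):
            np.testing.assert_allclose(A, np.linalg.solve(XtWX, X.T @ W), atol=1e-9)


class TestExactFullEfficiency:
    def test_sur_identical_designs(self, rng):
        """Identical X across measures with Z a shared sub-matrix: the
        separated GLS fixed effects are fully efficient."""
        for trial in range(5):
            subjects = make_sur_subjects(rng, n_subjects=int(rng.integers(1, 4)))
            true_c = bivariate_components(
                "A", rho_b=rng.uniform(-0.9, 0.9), rho_r=rng.uniform(-0.9, 0.9)
            )
            sep = separate_components(true_c)
            num = fixed_effects_mse(subjects, true_c, true_c)
            den = fixed_effects_mse(subjects, sep, true_c)
            assert mse_ratio(num, den) == pytest.approx(1.0, abs=1e-10)

    def test_zero_cross_covariance_all_ratios_one(self, rng):
        subject = make_bivariate_subject(n1=6, n2=3)
        true_c = separate_components(bivariate_components("B", 0.8, 0.7, 0.3))
        sep = separate_components(true_c)
        for f, kw in [
            (fixed_effects_mse, {}),
            (random_effects_mse, {"beta_known": True}),
            (random_effects_mse, {"beta_known": False}),
            (predicted_values_mse, {"beta_known": True}),
        ]:
            num = f([subject], true_c, true_c, **kw)
            den = f([subject], sep, true_c, **kw)
            assert mse_ratio(num, den) == pytest.approx(1.0, abs=1e-10)

    def test_single_measure_ratio_one(self, rng):
        t = np.linspace(-1, 1, 5)
        X = np.column_stack([np.ones(5), t])
        s = SubjectDesign("s", (MarkerDesign("m1", t, X, X),))
        comps = CovarianceComponents(np.eye(2), np.array([[1.0]]), (2,))
        num = fixed_effects_mse([s], comps, comps)
        den = fixed_effects_mse([s], separate_components(comps), comps)
        assert mse_ratio(num, den) == pytest.approx(1.0, abs=1e-12)


class TestDecompositionStructure:
    def test_additivity_and_labels(self, bivariate_cell):
        subject, true_c, sep = bivariate_cell
        dec = random_effects_mse(subject, sep, true_c, beta_known=True)
        assert dec.mse == pytest.approx(dec.squared_bias + dec.variance, rel=1e-10)
        assert dec.mse == pytest.approx(dec.per_coordinate.sum(), rel=1e-12)
        assert dec.coordinate_labels == (
            "m1:intercept", "m1:slope", "m2:intercept", "m2:slope",
        )

    def test_fixed_effects_unbiased(self, bivariate_cell):
        subject, true_c, sep = bivariate_cell
        for w in (true_c, sep):
            dec = fixed_effects_mse([subject], w, true_c)
            assert dec.squared_bias == 0.0

    def test_selection_ratios(self, bivariate_cell):
        subject, true_c, sep = bivariate_cell
        num = random_effects_mse(subject, true_c, true_c, beta_known=True)
        den = random_effects_mse(subject, sep, true_c, beta_known=True)
        assert mse_ratio(num, num) == pytest.approx(1.0)
        r_all = mse_ratio(num, den)
        r_m2 = mse_ratio(num, den, "measure:m2")
        r_int = mse_ratio(num, den, "intercept")
        assert 0 < r_m2 <= 1 + 1e-9 and 0 < r_int <= 1 + 1e-9
        assert r_all == pytest.approx(num.mse / den.mse)

    def test_degenerate_denominator_errors(self, bivariate_cell):
        subject, true_c, _ = bivariate_cell
        num = random_effects_mse(subject, true_c, true_c, beta_known=True)
        zero = type(num)(
            np.zeros_like(num.per_coordinate_bias2),
            np.zeros_like(num.per_coordinate_var),
            num.coordinate_labels,
        )
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            mse_ratio(num, zero)


class TestOptimalityAndSymmetry:
    def test_blup_optimality_random_configurations(self, rng):
        """The combined working model equals the truth, so its predictor is
        MSE-optimal: every ratio is at most 1."""
        from jointeff.validation import random_configuration

        for seed in rng.integers(0, 2**31 - 1, size=8):
            subjects, true_c = random_configuration(int(seed))
            sep = separate_components(true_c)
            for beta_known in (True, False):
                num = random_effects_mse(subjects, true_c, true_c, beta_known=beta_known)
                den = random_effects_mse(subjects, sep, true_c, beta_known=beta_known)
                assert num.mse <= den.mse + 1e-9
                p_num = predicted_values_mse(subjects, true_c, true_c, beta_known=beta_known)
                p_den = predicted_values_mse(subjects, sep, true_c, beta_known=beta_known)
                assert p_num.mse <= p_den.mse + 1e-9

    def test_sign_flip_symmetry(self):
        """Negating both cross-measure correlations leaves every MSE
        unchanged (equivalent to negating the measure-2 data)."""
        subject = make_bivariate_subject(n1=6, n2=4)
        for case in ("A", "B", "C"):
            a = bivariate_components(case, 0.7, 0.6, 0.3)
            b = bivariate_components(case, -0.7, -0.6, 0.3)
            for comps in ("x",):
                dec_a = random_effects_mse(subject, a, a, beta_known=True)
                dec_b = random_effects_mse(subject, b, b, beta_known=True)
                np.testing.assert_allclose(
                    dec_a.per_coordinate, dec_b.per_coordinate, atol=1e-10
                )


class TestStudyFrontEnd:
    def test_results_tables_and_summary(self, rng):
        subjects = [
            make_bivariate_subject(n1=6, n2=4, subject_id="a"),
            make_bivariate_subject(n1=6, n2=2, subject_id="b"),
        ]
        true_c = bivariate_components("B", 0.7, 0.5, 0.2)
        res = EfficiencyStudy(subjects, true_c, beta_known=False).fit()
        tab = res.random_effects_table()
        assert set(tab.columns) == {"m1", "m2"}
        assert ((tab > 0) & (tab <= 1 + 1e-9)).all().all()
        beta_tab = res.fixed_effects_table()
        assert beta_tab.iloc[0]["Overall"] <= 1 + 1e-9
        tidy = res.to_tidy()
        assert {"subject", "estimand", "working_model", "mse"} <= set(tidy.columns)
        assert "separated" in res.summary() or "combined" in res.summary()

    def test_mean_of_ratios_option(self, rng):
        subjects = [
            make_bivariate_subject(n1=6, n2=4, subject_id="a"),
            make_bivariate_subject(n1=6, n2=2, subject_id="b"),
        ]
        true_c = bivariate_components("A", 0.8, 0.8)
        res = EfficiencyStudy(subjects, true_c, beta_known=True).fit()
        rom = res.ratio("b", how="ratio_of_means")
        mor = res.ratio("b", how="mean_of_ratios")
        assert 0 < rom <= 1 + 1e-9 and 0 < mor <= 1 + 1e-9
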