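import numpy as np
import pandas as pd
import pytest

from jointeff.cohort import (
    MEASURES,
    CohortSpec,
    build_cohort_design,
    default_components,
    simulate_cohort,
)
from jointeff.covariance import separate_components
from jointeff.estimation import (
    UnivariateLMM,
    cross_covariance_moments,
    empirical_yearly_correlation,
    fit_separated_lmm,
    implied_yearly_correlation,
)


@pytest.fixture(scope="module")
def cohort_m500():
    tab = simulate_cohort(CohortSpec(m=500, seed=17))
    subjects, names, basis, values = build_cohort_design(
        tab.records, tab.covariates, return_values=True
    )
    return tab, subjects, values


class TestUnivariateLMM:
    def test_parameter_recovery(self, cohort_m500):
        """ML estimates approach the generating variance components."""
        tab, subjects, values = cohort_m500
        comps = tab.spec.components
        for mid in ("pFVC", "mRSS"):
            k = MEASURES.index(mid)
            res = fit_separated_lmm(subjects, values, mid)
            assert res.converged
            Dk = comps.D[2 * k : 2 * k + 2, 2 * k : 2 * k + 2]
            # sampling sd of a variance component at m = 500 is ~6-10%
            # relative, so 15% here; the tighter 10% bound runs at m = 2000
            assert res.sigma2 == pytest.approx(comps.R[k, k], rel=0.15)
            assert res.D[0, 0] == pytest.approx(Dk[0, 0], rel=0.15)
            assert res.D[1, 1] == pytest.approx(Dk[1, 1], rel=0.15)

    def test_loglik_increases(self, cohort_m500):
        _, subjects, values = cohort_m500
        res = fit_separated_lmm(subjects, values, "EF")
        diffs = np.diff(res.loglike_trace)
        assert np.all(diffs > -1e-6)  # monotone up to roundoff

    def test_single_subject_rejected(self, cohort_m500):
        _, subjects, values = cohort_m500
        with pytest.raises(ValueError, match="single subject"):
            UnivariateLMM(subjects[:1], values[:1], "pFVC")

    def test_matches_statsmodels_mixedlm(self):
        """Independent ML oracle: statsmodels MixedLM on a small cohort."""
        import statsmodels.api as sm

        tab = simulate_cohort(CohortSpec(m=120, seed=33))
        empty_cov = tab.covariates[[]]
        subjects, names, basis, values = build_cohort_design(
            tab.records, empty_cov, return_values=True
        )
        mine = fit_separated_lmm(subjects, values, "pFVC")

        rec = tab.records[tab.records.measure == "pFVC"].sort_values(
            ["subject_id", "time"], kind="mergesort"
        )
        X = np.column_stack([np.ones(len(rec)), basis(rec.time.to_numpy())])
        Z = np.column_stack([np.ones(len(rec)), rec.time.to_numpy()])
        mod = sm.MixedLM(
            rec.value.to_numpy(), X, groups=rec.subject_id.to_numpy(), exog_re=Z
        )
        ref = mod.fit(reml=False, method="lbfgs", maxiter=500)
        np.testing.assert_allclose(mine.beta, ref.fe_params, atol=2e-3)
        np.testing.assert_allclose(
            mine.D, ref.cov_re.to_numpy() if hasattr(ref.cov_re, "to_numpy") else ref.cov_re,
            rtol=0.02, atol=1e-5,
        )
        assert mine.sigma2 == pytest.approx(ref.scale, rel=0.02)
        assert mine.llf == pytest.approx(ref.llf, abs=0.5)

    def test_summary_mentions_fit(self, cohort_m500):
        _, subjects, values = cohort_m500
        res = fit_separated_lmm(subjects, values, "RVSP")
        s = res.summary()
        assert "RVSP" in s and "sigma2" in s


class TestCrossCovarianceMoments:
    def test_zero_cross_truth_recovered_as_zero(self):
        spec = CohortSpec(
            m=400, seed=29, components=separate_components(default_components())
        )
        tab = simulate_cohort(spec)
        subjects, names, basis, values = build_cohort_design(
            tab.records, tab.covariates, return_values=True
        )
        fits = {mid: fit_separated_lmm(subjects, values, mid) for mid in MEASURES}
        est = cross_covariance_moments(subjects, values, fits)
        D = est.components.D
        sd = np.sqrt(np.diag(D))
        corr = D / np.outer(sd, sd)
        mask = np.ones((10, 10), bool)
        for sl in est.components.block_slices():
            mask[sl, sl] = False
        # unshrunken slope projections roughly double the sampling noise of
        # a plain correlation, so ~3 SE at m = 400 is ~0.25
        assert np.abs(corr[mask]).max() < 0.25
        off_R = est.components.R - np.diag(np.diag(est.components.R))
        assert np.abs(off_R).max() < 0.05

    def test_cross_correlation_recovery(self, cohort_m500):
        tab, subjects, values = cohort_m500
        fits = {mid: fit_separated_lmm(subjects, values, mid) for mid in MEASURES}
        est = cross_covariance_moments(subjects, values, fits)

        def corr(M):
            s = np.sqrt(np.diag(M))
            return M / np.outer(s, s)

        err = np.abs(corr(est.components.D) - corr(tab.spec.components.D))
        assert err.max() < 0.2  # m = 500; the m = 2000 bound is 0.1
        # shared-day residual correlation of the lung pair
        Rh = est.components.R
        Rt = tab.spec.components.R
        assert abs(Rh[0, 1] - Rt[0, 1]) < 0.05


class TestYearlyCorrelation:
    def _records(self, values, times, subjects, measure="m1"):
        return pd.DataFrame(
            {
                "subject_id": subjects,
                "measure": measure,
                "time": times,
                "value": values,
            }
        )

    def test_white_noise_near_zero_offdiag(self, rng):
        n_sub, n_year = 300, 5
        rows = []
        for i in range(n_sub):
            for yr in range(n_year):
                for mid in ("a", "b"):
                    rows.append((f"s{i}", mid, yr + 0.5, rng.normal()))
        rec = pd.DataFrame(rows, columns=["subject_id", "measure", "time", "value"])
        C = empirical_yearly_correlation(rec, years=range(n_year), measures=("a", "b"))
        M = C.to_numpy()
        off = M[~np.eye(len(M), dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.25

    def test_pure_random_intercept_block_one(self, rng):
        rows = []
        for i in range(100):
            level = rng.normal()
            for yr in range(4):
                rows.append((f"s{i}", "a", yr + 0.2, level))
        rec = pd.DataFrame(rows, columns=["subject_id", "measure", "time", "value"])
        C = empirical_yearly_correlation(rec, years=range(4), measures=("a",))
        np.testing.assert_allclose(C.to_numpy(), 1.0, atol=1e-10)

    def test_sparse_cells_marked_missing(self, rng):
        rec = self._records([1.0, 2.0], [0.5, 1.5], ["s1", "s2"])
        C = empirical_yearly_correlation(rec, years=range(2), measures=("m1",))
        assert C.isna().any().any()

    def test_implied_separated_zero_cross(self):
        comps = default_components()
        sep = separate_components(comps)
        C = implied_yearly_correlation(sep, MEASURES)
        n_y = 11
        block = C.to_numpy()[:n_y, n_y : 2 * n_y]  # pFVC x pDLCO
        assert np.abs(block).max() == 0.0

    def test_implied_zero_D_identity(self):
        from jointeff import CovarianceComponents

        comps = CovarianceComponents(
            np.zeros((4, 4)), np.eye(2), q_per_measure=(2, 2)
        )
        C = implied_yearly_correlation(comps, ("a", "b"), years=range(3))
        np.testing.assert_allclose(C.to_numpy(), np.eye(6), atol=1e-12)

    def test_empirical_matches_implied_on_simulated_cohort(self):
        tab = simulate_cohort(CohortSpec(m=1500, seed=41))
        # restrict to (year, year) cells shared by >= 100 subjects; sparser
        # pairwise-complete cells are dominated by correlation sampling noise
        emp = empirical_yearly_correlation(
            tab.records, measures=MEASURES, min_subjects=100
        )
        imp = implied_yearly_correlation(tab.spec.components, MEASURES)
        diff = (emp - imp).to_numpy()
        assert np.nanmean(np.abs(diff)) <= 0.1
        # the lung-lung cross block is strongly positive, EF rows near zero
        lung = emp.loc[
            [f"pFVC:{y}" for y in range(11)], [f"pDLCO:{y}" for y in range(11)]
        ].to_numpy()
        assert np.nanmean(lung) > 0.3
        ef = emp.loc[
            [f"EF:{y}" for y in range(11)],
            [f"pFVC:{y}" for y in range(11)] + [f"mRSS:{y}" for y in range(11)],
        ].to_numpy()
        assert abs(np.nanmean(ef)) < 0.1
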