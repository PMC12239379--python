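"""Regression machinery: mixed model, robust scan, FDR, inflation, residuals."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epitrain import (
    DomainError,
    bh_fdr,
    compute_inflation,
    dnamc_association,
    fit_mixed_ewas,
    fit_robust_ewas,
    residualize_by_timepoint,
    seasonality_terms,
    sensitivity_refit,
)
from epitrain.ewas import fit_random_intercept

from conftest import make_sheet


def _paired_m_matrix(rng, n_subjects=40, n_probes=6, delta=0.0):
    """Balanced 2-timepoint M matrix with subject intercepts."""
    sheet = make_sheet(n_subjects, timepoints=("T0", "T90"))
    subj = rng.normal(0, 0.7, (n_probes, n_subjects))
    noise = rng.normal(0, 0.5, (n_probes, 2 * n_subjects))
    cols = sheet["sample_id"].tolist()
    m = np.repeat(subj, 2, axis=1) + noise
    is_t90 = np.array([c.endswith("T90") for c in cols])
    m[:, is_t90] += delta
    return pd.DataFrame(m, index=[f"cg{i}" for i in range(n_probes)],
                        columns=cols), sheet


class TestRandomInterceptSolver:
    def test_agrees_with_generic_mixed_model_fitter(self, rng):
        """Independent oracle: statsmodels MixedLM on the same data."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        n_sub, tps = 40, 3
        groups = np.repeat(np.arange(n_sub), tps)
        tp = np.tile(np.arange(tps), n_sub)
        x = np.column_stack([np.ones(n_sub * tps), tp == 1, tp == 2,
                             rng.normal(size=n_sub * tps)]).astype(float)
        for _ in range(5):
            y = (rng.normal(size=n_sub * tps)
                 + np.repeat(rng.normal(size=n_sub), tps) * 0.8
                 + (tp == 2) * 0.4)
            ours = fit_random_intercept(y, x, groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = MixedLM(y, x, groups=groups).fit(reml=True)
            np.testing.assert_allclose(ours.params, ref.fe_params, atol=1e-4)
            s2u_ref = float(np.asarray(ref.cov_re)[0, 0])
            assert ours.sigma2_e == pytest.approx(ref.scale, rel=1e-3)
            assert ours.sigma2_u == pytest.approx(s2u_ref, rel=1e-3, abs=1e-5)
            # exact GLS covariance at the oracle's variance estimates
            # (MixedLM's own bse_fe uses a numerical Hessian and is less exact)
            v = np.kron(np.eye(n_sub), ref.scale * np.eye(tps) + s2u_ref)
            cov_ref = np.linalg.inv(x.T @ np.linalg.solve(v, x))
            np.testing.assert_allclose(ours.bse, np.sqrt(np.diag(cov_ref)),
                                       rtol=1e-3)

    def test_zero_variance_component_flagged_singular(self, rng):
        groups = np.repeat(np.arange(30), 3)
        x = np.column_stack([np.ones(90), rng.normal(size=90)])
        noise = rng.normal(size=90)
        # within-subject centering removes all between-subject variance, so
        # the REML variance component sits at the zero boundary
        y = noise - np.repeat(noise.reshape(30, 3).mean(axis=1), 3)
        fit = fit_random_intercept(y, x, groups)
        assert fit.singular


class TestMixedEwas:
    def test_balanced_pairwise_equals_within_subject_difference(self, rng):
        """Closed form: the T90 coefficient is the mean paired difference."""
        m, sheet = _paired_m_matrix(rng, delta=0.3)
        res = fit_mixed_ewas(m, sheet, covariates=(), contrast=("T90", "T0"))
        t90 = sheet[sheet.timepoint == "T90"]["sample_id"]
        t0 = sheet[sheet.timepoint == "T0"]["sample_id"]
        for probe in m.index:
            paired = (m.loc[probe, t90.to_numpy()].to_numpy()
                      - m.loc[probe, t0.to_numpy()].to_numpy()).mean()
            assert res.loc[probe, "estimate"] == pytest.approx(paired, abs=1e-8)

    def test_spiked_probe_detected_with_positive_sign(self, rng):
        m, sheet = _paired_m_matrix(rng, n_subjects=200, n_probes=3, delta=1.0)
        res = fit_mixed_ewas(m, sheet, covariates=(), contrast=("T90", "T0"))
        assert (res["p"] < 1e-5).all()
        assert (res["estimate"] > 0).all()

    def test_overall_model_reports_joint_test(self, small_cohort):
        from epitrain import beta_to_m
        m = beta_to_m(small_cohort.betas.iloc[:20])
        res = fit_mixed_ewas(m, small_cohort.samples,
                             cell_fractions=small_cohort.cell_fractions)
        assert res["p"].between(0, 1).all()
        assert (res["model"] != "na").all()
        assert (res["q"] >= res["p"]).all()

    def test_sex_stratified_equals_manual_subset(self, small_cohort):
        from epitrain import beta_to_m
        m = beta_to_m(small_cohort.betas.iloc[:10])
        sheet = small_cohort.samples
        subset = sheet.set_index("sample_id")["sex"] == "F"
        strat = fit_mixed_ewas(m, sheet, cell_fractions=None,
                               covariates=("age", "plate"), subset=subset)
        manual = fit_mixed_ewas(m, sheet[sheet["sex"] == "F"],
                                cell_fractions=None,
                                covariates=("age", "plate"))
        pd.testing.assert_frame_equal(strat, manual)

    def test_missing_values_complete_case(self, rng):
        m, sheet = _paired_m_matrix(rng, n_subjects=30)
        m.iloc[0, :6] = np.nan
        res = fit_mixed_ewas(m, sheet, covariates=(), contrast=("T90", "T0"))
        assert res.iloc[0]["n_used"] == 54
        assert np.isfinite(res.iloc[0]["p"])


class TestRobustEwas:
    def test_matches_ols_without_outliers(self, rng):
        """Oracle equivalence: Gaussian errors, no outliers, n=200."""
        import statsmodels.api as sm

        n, n_probes = 200, 200
        sheet = make_sheet(n, timepoints=("T0",))
        mvals = rng.normal(size=(n_probes, n))
        slopes = rng.normal(0, 1.0, n_probes)  # unit-scale effects
        m = pd.DataFrame(mvals, index=[f"cg{i}" for i in range(n_probes)],
                         columns=sheet["sample_id"])
        rel_errs = []
        ti = pd.Series(rng.normal(size=n), index=sheet["subject_id"])
        y_signal = (mvals * slopes[:, None])
        for i, probe in enumerate(m.index):
            yv = y_signal[i] + ti.to_numpy()
            rob = fit_robust_ewas(m.iloc[[i]], pd.Series(yv, index=ti.index),
                                  sheet, covariates=("age",))
            x = np.column_stack([mvals[i], np.ones(n),
                                 sheet["age"].to_numpy(dtype=float)])
            ols = sm.OLS(yv, x).fit()
            rel_errs.append(rob["estimate"].iloc[0] - ols.params[0])
        rms = np.sqrt(np.mean(np.square(rel_errs)))
        scale = np.sqrt(np.mean(np.square(slopes)))
        assert rms / scale < 0.02

    def test_robust_beats_ols_under_gross_outlier(self, rng):
        import statsmodels.api as sm

        wins = 0
        n = 80
        for rep in range(100):
            x = rng.normal(size=n)
            x[0] = 3.0  # leverage point where an outcome outlier tilts OLS
            y = 0.5 * x + rng.normal(size=n)
            y[0] += 10.0  # one gross outlier in the outcome
            xx = np.column_stack([x, np.ones(n)])
            ols = sm.OLS(y, xx).fit().params[0]
            from epitrain.ewas import _rlm_fit
            rob = _rlm_fit(y, xx)[0].params[0]
            if abs(rob - 0.5) < abs(ols - 0.5):
                wins += 1
        assert wins >= 90

    def test_constant_probe_reported(self, rng):
        sheet = make_sheet(30, timepoints=("T0",))
        m = pd.DataFrame(np.ones((1, 30)), index=["cg0"],
                         columns=sheet["sample_id"])
        ti = pd.Series(rng.normal(size=30),
                       index=sheet["subject_id"])
        res = fit_robust_ewas(m, ti, sheet, covariates=("age",))
        assert res.iloc[0]["reason"] == "constant predictor"
        assert np.isnan(res.iloc[0]["p"])


class TestResidualize:
    def test_exact_linear_gives_zero_residuals(self, rng):
        sheet = make_sheet(30, timepoints=("T0", "T90"))
        cf = pd.DataFrame(rng.dirichlet(np.ones(3), 60),
                          index=sheet["sample_id"], columns=list("abc"))
        m = pd.DataFrame(
            (cf.to_numpy() @ np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5]])).T,
            index=["cg0", "cg1"], columns=sheet["sample_id"])
        resid = residualize_by_timepoint(m, sheet, covariates=(),
                                         cell_fractions=cf)
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-10)

    def test_covariate_free_residuals_are_centered_values(self, rng):
        sheet = make_sheet(20, timepoints=("T0", "T90"))
        m = pd.DataFrame(rng.normal(size=(4, 40)),
                         index=[f"cg{i}" for i in range(4)],
                         columns=sheet["sample_id"])
        resid = residualize_by_timepoint(m, sheet, covariates=())
        for tp in ("T0", "T90"):
            ids = sheet.loc[sheet.timepoint == tp, "sample_id"]
            sub = m[ids.to_numpy()]
            np.testing.assert_allclose(
                resid[ids.to_numpy()].to_numpy(),
                sub.to_numpy() - sub.to_numpy().mean(axis=1, keepdims=True),
                atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self, small_cohort):
        from epitrain import beta_to_m
        m = beta_to_m(small_cohort.betas.iloc[:15])
        resid = residualize_by_timepoint(
            m, small_cohort.samples,
            cell_fractions=small_cohort.cell_fractions)
        sheet = small_cohort.samples
        for tp in ("T0", "T14", "T90"):
            ids = sheet.loc[sheet.timepoint == tp, "sample_id"].to_numpy()
            cf = small_cohort.cell_fractions.loc[ids]
            r = resid[ids].to_numpy()
            for k in range(cf.shape[1] - 1):
                c = cf.iloc[:, k].to_numpy()
                c = c - c.mean()
                corr = r @ c / np.sqrt((r**2).sum(axis=1) * (c**2).sum())
                assert np.abs(corr).max() < 1e-8

    def test_too_few_samples_raises(self, rng):
        sheet = make_sheet(2, timepoints=("T0", "T90"))
        cf = pd.DataFrame(rng.dirichlet(np.ones(5), 4),
                          index=sheet["sample_id"])
        m = pd.DataFrame(rng.normal(size=(3, 4)), columns=sheet["sample_id"])
        with pytest.raises(DomainError, match="fewer samples"):
            residualize_by_timepoint(m, sheet, covariates=(), cell_fractions=cf)


class TestDnamcAssociation:
    def test_spiked_slope_recovered(self, rng):
        n = 200
        sheet = make_sheet(n, timepoints=("T0", "T90"))
        change = rng.normal(size=(5, n))
        resid = pd.DataFrame(np.zeros((5, 2 * n)),
                             index=[f"cg{i}" for i in range(5)],
                             columns=sheet["sample_id"])
        is90 = sheet["timepoint"].to_numpy() == "T90"
        resid.loc[:, is90] = change
        ti = pd.Series(0.5 * change[0] + rng.normal(size=n),
                       index=sheet["subject_id"].unique())
        res = dnamc_association(resid, sheet, ("T90", "T0"), ti)
        assert res.iloc[0]["p"] < 1e-5 and res.iloc[0]["estimate"] > 0
        assert (res.iloc[1:]["p"] > 1e-5).all()

    def test_permuted_ti_is_null(self, rng):
        n = 100
        sheet = make_sheet(n, timepoints=("T0", "T90"))
        resid = pd.DataFrame(rng.normal(size=(100, 2 * n)),
                             index=[f"cg{i}" for i in range(100)],
                             columns=sheet["sample_id"])
        ti = pd.Series(rng.permutation(n).astype(float),
                       index=sheet["subject_id"].unique())
        res = dnamc_association(resid, sheet, ("T90", "T0"), ti)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_identical_residuals_error(self, rng):
        n = 20
        sheet = make_sheet(n, timepoints=("T0", "T90"))
        base = rng.normal(size=(3, n))
        resid = pd.DataFrame(np.repeat(base, 2, axis=1),
                             index=[f"cg{i}" for i in range(3)],
                             columns=sheet["sample_id"])
        ti = pd.Series(rng.normal(size=n), index=sheet["subject_id"].unique())
        with pytest.raises(DomainError, match="constant predictor"):
            dnamc_association(resid, sheet, ("T90", "T0"), ti)

    def test_too_few_pairs_error(self, rng):
        sheet = make_sheet(5, timepoints=("T0", "T90"))
        resid = pd.DataFrame(rng.normal(size=(2, 10)),
                             columns=sheet["sample_id"])
        ti = pd.Series(rng.normal(size=5), index=sheet["subject_id"].unique())
        with pytest.raises(DomainError, match="pairs"):
            dnamc_association(resid, sheet, ("T90", "T0"), ti)


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=10))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_step_up(self, pvals):
        """Oracle: direct step-up enumeration q_i = min over j>=i of m*p_(j)/j."""
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_nan_excluded_and_reinserted(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0]) and np.isfinite(q[2])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.5])


class TestInflation:
    def test_uniform_p_gives_unit_lambda(self, rng):
        p = rng.random(100_000)
        assert compute_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_all_half_is_exactly_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lam = compute_inflation(np.full(200, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_halved_p_inflates(self, rng):
        p = rng.random(10_000)
        assert compute_inflation(p / 2) > 1.0

    def test_min_count_enforced(self):
        with pytest.raises(DomainError):
            compute_inflation([0.5] * 10)


class TestSeasonality:
    def test_six_months_apart_opposite_sign(self):
        t = seasonality_terms(pd.Series([pd.Timestamp("2020-03-01"),
                                         pd.Timestamp("2020-09-01")]))
        assert np.sign(t["season_sin"].iloc[0]) == -np.sign(t["season_sin"].iloc[1])

    def test_same_date_different_years_identical(self):
        t = seasonality_terms(pd.Series([pd.Timestamp("2019-05-10"),
                                         pd.Timestamp("2021-05-10")]))
        np.testing.assert_allclose(t.iloc[0].to_numpy(), t.iloc[1].to_numpy(),
                                   atol=1e-12)

    def test_uniform_dates_near_zero_mean(self):
        dates = pd.date_range("2020-01-01", periods=365, freq="D")
        t = seasonality_terms(pd.Series(dates))
        assert abs(t["season_sin"].mean()) < 0.02
        assert abs(t["season_cos"].mean()) < 0.02

    def test_missing_date_propagates(self):
        t = seasonality_terms(pd.Series([pd.Timestamp("2020-01-01"), pd.NaT]))
        assert np.isnan(t["season_sin"].iloc[1])


class TestSensitivity:
    def test_identical_variant_full_concordance(self, small_cohort):
        from epitrain import beta_to_m
        m = beta_to_m(small_cohort.betas.loc[
            list(small_cohort.ledger.trajectory)])
        base = fit_mixed_ewas(m, small_cohort.samples,
                              cell_fractions=small_cohort.cell_fractions)
        refit, report = sensitivity_refit(
            m, small_cohort.samples, base, "base",
            cell_fractions=small_cohort.cell_fractions, suggestive_p=0.05)
        assert report["frac_same_direction"] == 1.0
        assert report["frac_retained_suggestive"] == 1.0

    def test_empty_age_subset_errors(self, rng):
        sheet = make_sheet(10)
        sheet["age"] = 20.0
        m = pd.DataFrame(rng.normal(size=(2, len(sheet))),
                         columns=sheet["sample_id"])
        with pytest.raises(DomainError, match="age>30"):
            sensitivity_refit(m, sheet, pd.DataFrame({"p": [], "estimate": []}),
                              "age_gt_30")

    def test_cell12_variant_swaps_the_deconvolution_panel(self, rng):
        m, sheet = _paired_m_matrix(rng, n_subjects=60, n_probes=3, delta=0.8)
        cf12 = pd.DataFrame(rng.dirichlet(np.ones(12), len(sheet)),
                            index=sheet["sample_id"],
                            columns=[f"C{i}" for i in range(12)])
        base = fit_mixed_ewas(m, sheet, covariates=(), contrast=("T90", "T0"))
        refit, report = sensitivity_refit(m, sheet, base, "cell12",
                                          covariates=(),
                                          cell_fractions_12=cf12,
                                          contrast=("T90", "T0"),
                                          suggestive_p=0.05)
        assert report["frac_same_direction"] == 1.0
        with pytest.raises(DomainError, match="12-type"):
            sensitivity_refit(m, sheet, base, "cell12", covariates=())

    def test_seasonality_variant_adds_terms_and_keeps_effects(self, rng):
        m, sheet = _paired_m_matrix(rng, n_subjects=120, n_probes=4, delta=1.0)
        base = fit_mixed_ewas(m, sheet, covariates=(), contrast=("T90", "T0"))
        refit, report = sensitivity_refit(m, sheet, base, "seasonality",
                                          covariates=(), contrast=("T90", "T0"))
        assert report["n_base_suggestive"] == 4
        assert report["frac_retained_suggestive"] >= 0.9
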