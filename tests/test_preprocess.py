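"""Transforms and QC: beta<->M, Tukey masking, INT, TI, deconvolution, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epitrain import (
    DomainError,
    beta_to_m,
    compute_ti,
    deconvolve_cells,
    inverse_rank_normalize,
    m_to_beta,
    pca_covariate_scan,
    tukey_mask,
)
from epitrain.preprocess import mask_matrix_outliers


class TestBetaM:
    @pytest.mark.parametrize("beta,expected", [
        (0.5, 0.0),          # symmetry point of the logit
        (0.8, 2.0),          # log2(4)
        (0.2, -2.0),         # antisymmetry partner of 0.8
    ])
    def test_known_values(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self):
        assert beta_to_m(0.2) == pytest.approx(-beta_to_m(0.8), abs=1e-12)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            beta_to_m(1.2)
        with pytest.raises(DomainError):
            beta_to_m(-0.1)

    def test_exact_zero_one_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            m = beta_to_m(np.array([0.0, 1.0]))
        assert np.isfinite(m).all()
        assert m[0] == pytest.approx(-m[1], abs=1e-6)

    def test_na_propagates_in_frames(self):
        df = pd.DataFrame({"a": [0.5, np.nan]})
        out = beta_to_m(df)
        assert out.iloc[0, 0] == 0.0 and np.isnan(out.iloc[1, 0])


class TestTukeyMask:
    def test_hand_computed_vector(self):
        # Q1=2, Q3=4 (type-7), IQR=2, upper fence 4 + 3*2 = 10
        masked, mask = tukey_mask([1, 2, 3, 4, 100])
        assert list(mask) == [False, False, False, False, True]
        assert np.isnan(masked[4]) and np.array_equal(masked[:4], [1, 2, 3, 4])

    def test_constant_vector_untouched(self):
        masked, mask = tukey_mask([5.0] * 6)
        assert not mask.any()

    def test_clean_symmetric_data_untouched(self):
        masked, mask = tukey_mask(np.arange(20.0))
        assert not mask.any()

    def test_idempotent(self, rng):
        v = rng.normal(size=50)
        v[3] = 40.0
        once, _ = tukey_mask(v)
        twice, mask2 = tukey_mask(once)
        assert not mask2.any()
        np.testing.assert_array_equal(once, twice)

    def test_errors(self):
        with pytest.raises(DomainError):
            tukey_mask([np.nan, np.nan, np.nan, np.nan])
        with pytest.raises(DomainError):
            tukey_mask([1.0, 2.0, 3.0])

    def test_matrix_wrapper_masks_per_probe(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 30)))
        mat.iloc[2, 7] = 1e3
        out = mask_matrix_outliers(mat)
        assert np.isnan(out.iloc[2, 7])
        assert out.drop(index=2).notna().all().all()


class TestInverseRankNormalize:
    def test_middle_of_three_maps_to_zero(self):
        z = inverse_rank_normalize([10.0, -3.0, 5.0])
        assert z[2] == pytest.approx(0.0, abs=1e-12)

    def test_ties_get_equal_scores(self):
        z = inverse_rank_normalize([1.0, 2.0, 2.0, 3.0])
        assert z[1] == z[2]

    def test_rank_preserving(self, rng):
        x = rng.normal(size=40)
        z = inverse_rank_normalize(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)

    def test_blom_formula(self):
        # n=4 distinct values: z_r = Phi^-1((r - 3/8) / 4.25)
        z = inverse_rank_normalize([1.0, 2.0, 3.0, 4.0])
        expected = stats.norm.ppf((np.arange(1, 5) - 0.375) / 4.25)
        np.testing.assert_allclose(z, expected, atol=1e-12)

    def test_errors(self):
        with pytest.raises(DomainError):
            inverse_rank_normalize([1.0, 1.0, 1.0])
        with pytest.raises(DomainError):
            inverse_rank_normalize([1.0, np.nan])


class TestComputeTI:
    @staticmethod
    def table(conc_t0, conc_t90, batch=None):
        n = len(conc_t0)
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "cytokine": "IFNg",
            "conc_T0": conc_t0,
            "conc_T90": conc_t90,
            "batch": batch if batch is not None else ["B1"] * n,
        })

    def test_tenfold_increase_gives_one(self):
        t = self.table([10.0] * 5 + [20.0], [100.0] * 5 + [40.0])
        out = compute_ti(t)
        assert out.loc[0, "ti_raw"] == pytest.approx(1.0)

    def test_no_change_gives_zero(self):
        t = self.table([7.0] * 5, [7.0] * 5)
        assert (compute_ti(t)["ti_raw"] == 0).all()

    def test_batch_residualization_removes_batch_means(self, rng):
        n = 40
        raw = rng.normal(size=n)
        batch = np.where(np.arange(n) < 20, "B1", "B2")
        shift = np.where(batch == "B1", 0.0, 0.7)
        c0 = 10.0 ** rng.normal(2, 0.3, n)
        c90 = c0 * 10.0 ** (raw + shift)
        out = compute_ti(self.table(c0, c90, batch=list(batch)))
        grand = out["ti_corrected"].mean()
        for b in ("B1", "B2"):
            grp = out.loc[np.asarray(batch) == b, "ti_corrected"]
            assert grp.mean() == pytest.approx(grand, abs=1e-10)

    def test_unit_invariance(self, rng):
        c0 = rng.uniform(5, 50, 12)
        c90 = rng.uniform(5, 50, 12)
        a = compute_ti(self.table(c0, c90))
        b = compute_ti(self.table(c0 * 37.5, c90 * 37.5))
        np.testing.assert_allclose(a["ti_raw"], b["ti_raw"], atol=1e-12)

    def test_nonpositive_concentration_names_subject(self):
        t = self.table([10.0, -1.0, 5.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        with pytest.raises(DomainError, match="S1"):
            compute_ti(t)

    def test_missing_pair_dropped(self):
        t = self.table([10.0, np.nan, 5.0, 6.0, 7.0], [1.0] * 5)
        out = compute_ti(t)
        assert "S1" not in set(out["subject_id"])


class TestDeconvolution:
    @staticmethod
    def reference(rng, n_probes=60, k=6):
        vals = rng.uniform(0.05, 0.95, (n_probes, k))
        return pd.DataFrame(vals, index=[f"cg{i}" for i in range(n_probes)],
                            columns=[f"C{j}" for j in range(k)])

    def test_exact_mixture_recovered(self, rng):
        ref = self.reference(rng)
        f = rng.dirichlet(np.ones(6), size=8)
        mix = ref.to_numpy() @ f.T
        betas = pd.DataFrame(mix, index=ref.index,
                             columns=[f"s{i}" for i in range(8)])
        est = deconvolve_cells(betas, ref)
        np.testing.assert_allclose(est.to_numpy(), f, atol=1e-6)

    def test_pure_sample_gives_indicator(self, rng):
        ref = self.reference(rng)
        betas = ref[["C2"]].rename(columns={"C2": "pure"})
        est = deconvolve_cells(betas, ref)
        expected = np.zeros(6)
        expected[2] = 1.0
        np.testing.assert_allclose(est.loc["pure"].to_numpy(), expected, atol=1e-6)

    def test_noisy_mixture_error_bound(self, rng):
        ref = self.reference(rng, n_probes=120)
        f = rng.dirichlet(np.ones(6), size=100)
        mix = ref.to_numpy() @ f.T + rng.normal(0, 0.02, (120, 100))
        betas = pd.DataFrame(np.clip(mix, 0, 1), index=ref.index,
                             columns=[f"s{i}" for i in range(100)])
        est = deconvolve_cells(betas, ref)
        mae = np.abs(est.to_numpy() - f).mean()
        assert mae < 0.05

    def test_fractions_on_simplex(self, rng):
        ref = self.reference(rng)
        betas = pd.DataFrame(rng.uniform(0.1, 0.9, (60, 5)), index=ref.index,
                             columns=[f"s{i}" for i in range(5)])
        est = deconvolve_cells(betas, ref)
        assert (est.to_numpy() >= 0).all()
        np.testing.assert_allclose(est.sum(axis=1), 1.0, atol=1e-8)

    def test_column_reordering_permutes_labels_only(self, rng):
        ref = self.reference(rng)
        betas = pd.DataFrame(rng.uniform(0.1, 0.9, (60, 4)), index=ref.index,
                             columns=list("abcd"))
        est1 = deconvolve_cells(betas, ref)
        est2 = deconvolve_cells(betas, ref[list(reversed(ref.columns))])
        np.testing.assert_allclose(est1.to_numpy(),
                                   est2[est1.columns].to_numpy(), atol=1e-8)

    def test_rank_deficient_reference_rejected(self, rng):
        ref = self.reference(rng)
        ref["C5"] = ref["C4"]
        betas = pd.DataFrame(rng.uniform(0.1, 0.9, (60, 2)), index=ref.index,
                             columns=["s0", "s1"])
        with pytest.raises(DomainError, match="rank"):
            deconvolve_cells(betas, ref)


class TestPcaScan:
    def test_injected_covariate_drives_pc1(self, rng):
        n_probes, n_samples = 150, 60
        driver = rng.normal(size=n_samples)
        x = rng.normal(0, 0.2, (n_probes, n_samples))
        x[:40] += np.outer(rng.normal(size=40) * 3, driver)
        m = pd.DataFrame(x, columns=[f"s{i}" for i in range(n_samples)])
        covs = pd.DataFrame({"driver": driver, "noise": rng.normal(size=n_samples)},
                            index=m.columns)
        res = pca_covariate_scan(m, covs, k=10)
        assert res.p_values["driver"].idxmin() == "PC1"
        assert res.p_values.loc["PC1", "driver"] < 1e-10

    def test_permuted_covariate_uniform(self, rng):
        m = pd.DataFrame(rng.normal(size=(200, 80)),
                         columns=[f"s{i}" for i in range(80)])
        covs = pd.DataFrame({"perm": rng.permutation(80)}, index=m.columns)
        res = pca_covariate_scan(m, covs, k=30)
        p = res.p_values["perm"].to_numpy(dtype=float)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_full_rank_cumulative_variance_is_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 12)),
                         columns=[f"s{i}" for i in range(12)])
        res = pca_covariate_scan(m, pd.DataFrame({"c": rng.normal(size=12)},
                                                 index=m.columns), k=12)
        assert res.cumulative_variance == pytest.approx(1.0, abs=1e-10)

    def test_constant_covariate_warns_and_nas(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 20)),
                         columns=[f"s{i}" for i in range(20)])
        covs = pd.DataFrame({"const": 1.0, "ok": rng.normal(size=20)},
                            index=m.columns)
        with pytest.warns(UserWarning, match="constant"):
            res = pca_covariate_scan(m, covs, k=5)
        assert res.p_values["const"].isna().all()
        assert res.p_values["ok"].notna().all()
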