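"""Preparation chain: censoring filter, imputation, standardisation, scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from hbmnet import (
    BiomarkerMatrix,
    DataError,
    censoring_summary,
    filter_by_censoring,
    impute_censored_ml,
    impute_missing_chained,
    log_transform,
    preprocess,
    residualize_covariates,
    select_single_biomarker,
    standardize_dilution,
    zscore_scale,
)

from conftest import make_bm


class TestCensoringSummary:
    def test_zero_censoring_gives_zero_fractions(self):
        bm = make_bm(np.full((10, 3), 2.0))
        s = censoring_summary(bm)
        assert (s["frac_below_loq"] == 0).all()

    def test_direct_count(self):
        cens = np.zeros((10, 1), bool)
        cens[:4, 0] = True
        vals = np.full((10, 1), 2.0)
        vals[:4] = np.nan
        bm = make_bm(vals, censored=cens, lod=[1.0])
        assert censoring_summary(bm)["frac_below_loq"].iloc[0] == pytest.approx(0.40)

    def test_mixed_missing_and_censored_hand_count(self):
        # 10 cells: 2 missing, 3 censored -> 3/8 of non-missing cells
        vals = np.full((10, 1), 2.0)
        cens = np.zeros((10, 1), bool)
        miss = np.zeros((10, 1), bool)
        cens[[0, 1, 2], 0] = True
        miss[[3, 4], 0] = True
        vals[:5] = np.nan
        bm = make_bm(vals, censored=cens, missing=miss, lod=[1.0])
        assert censoring_summary(bm)["frac_below_loq"].iloc[0] == pytest.approx(3 / 8)


class TestCensoringFilter:
    def _bm_with_fractions(self, counts, n=100):
        p = len(counts)
        vals = np.full((n, p), 2.0)
        cens = np.zeros((n, p), bool)
        for j, c in enumerate(counts):
            cens[:c, j] = True
            vals[:c, j] = np.nan
        return make_bm(vals, censored=cens, lod=[1.0] * p)

    def test_more_than_forty_percent_is_strict(self):
        bm = self._bm_with_fractions([39, 40, 41])
        kept, excluded = filter_by_censoring(bm, threshold=0.40)
        assert excluded == ["2"]          # only the 41% biomarker
        assert kept.biomarkers == ["0", "1"]

    def test_nothing_excluded_without_censoring(self):
        bm = self._bm_with_fractions([0, 0])
        kept, excluded = filter_by_censoring(bm)
        assert excluded == [] and kept.n_biomarkers == 2

    def test_zero_threshold_excludes_any_censoring(self):
        bm = self._bm_with_fractions([1, 0])
        _, excluded = filter_by_censoring(bm, threshold=0.0)
        assert excluded == ["0"]

    def test_threshold_out_of_range(self):
        bm = self._bm_with_fractions([0])
        with pytest.raises(DataError):
            filter_by_censoring(bm, threshold=1.5)


class TestLogTransform:
    def test_values_and_thresholds(self):
        bm = make_bm(np.array([[np.e, 1.0]]), lod=[0.5, 0.5])
        out = log_transform(bm)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.0)
        assert np.allclose(out.thresholds.to_numpy(), np.log(0.5))
        assert out.log_scale

    def test_non_positive_value_names_cell(self):
        bm = make_bm(np.array([[1.0], [1.0]]))
        bm.values.iloc[1, 0] = -2.0
        with pytest.raises(DataError, match="non-positive"):
            log_transform(bm)


class TestCensoredImputation:
    def test_truncated_normal_closed_form(self):
        # single biomarker, LOD at the mean of a standard normal: the
        # conditional mean below the limit is -sqrt(2/pi) ~ -0.7979
        rng = np.random.default_rng(0)
        z = rng.standard_normal(2000)
        cens = z < 0.0
        vals = np.where(cens, np.nan, z).reshape(-1, 1)
        bm = make_bm(vals, censored=cens.reshape(-1, 1), lod=[0.0], log_scale=True)
        out, diag = impute_censored_ml(bm)
        imputed = out.values.to_numpy()[cens, 0]
        assert diag["converged"]
        assert abs(imputed.mean() - (-np.sqrt(2 / np.pi))) < 0.05
        assert (imputed < 0.0).all()

    def test_independent_partner_is_ignored(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3000, 2))
        cens = np.zeros((3000, 2), bool)
        cens[:, 0] = X[:, 0] < 0.0
        vals = np.where(cens, np.nan, X)
        bm = make_bm(vals, censored=cens, lod=[0.0, -np.inf], log_scale=True)
        out, _ = impute_censored_ml(bm)
        imputed = out.values.to_numpy()[cens[:, 0], 0]
        partner = X[cens[:, 0], 1]
        # conditional mean barely depends on the independent partner
        slope = np.polyfit(partner, imputed, 1)[0]
        assert abs(slope) < 0.05
        assert abs(imputed.mean() - (-np.sqrt(2 / np.pi))) < 0.05

    def test_bivariate_conditional_oracle(self):
        # correlation 0.8: the imputed value must match the mean of the
        # truncated conditional density (numerical integration) and be
        # closer to it than the marginal truncated mean
        r = 0.8
        rng = np.random.default_rng(2)
        X = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], 4000)
        d = float(np.quantile(X[:, 0], 0.1))
        cens = np.zeros((4000, 2), bool)
        cens[:, 0] = X[:, 0] < d
        vals = np.where(cens, np.nan, X)
        bm = make_bm(vals, censored=cens, lod=[d, -np.inf], log_scale=True)
        out, _ = impute_censored_ml(bm)

        i = int(np.where(cens[:, 0])[0][0])
        y = X[i, 1]
        mu_c, sd_c = r * y, np.sqrt(1 - r**2)
        num = integrate.quad(lambda x: x * stats.norm.pdf(x, mu_c, sd_c), -20, d)[0]
        oracle = num / stats.norm.cdf(d, mu_c, sd_c)
        a = stats.norm.ppf(0.1)
        marginal = -stats.norm.pdf(a) / stats.norm.cdf(a)  # truncated below P10
        got = out.values.iloc[i, 0]
        assert got < d
        assert abs(got - oracle) < 0.1
        assert abs(got - oracle) < abs(got - marginal)

    def test_imputed_strictly_below_threshold(self, small_cohort):
        bm, cov, _ = small_cohort
        lbm = log_transform(standardize_dilution(bm, cov, "divide"))
        out, _ = impute_censored_ml(lbm)
        cens = lbm.censored.to_numpy()
        assert (out.values.to_numpy()[cens] < lbm.thresholds.to_numpy()[cens]).all()

    def test_all_censored_biomarker_rejected(self):
        vals = np.full((5, 1), np.nan)
        bm = make_bm(vals, censored=np.ones((5, 1), bool), lod=[0.0], log_scale=True)
        with pytest.raises(DataError):
            impute_censored_ml(bm)


class TestChainedImputation:
    def _cov(self, n=6):
        return pd.DataFrame(
            {"age": np.linspace(20, 70, n), "creatinine": np.ones(n)}
        )

    def test_no_missing_is_identity(self):
        bm = make_bm(np.arange(1.0, 13.0).reshape(6, 2), log_scale=True)
        out, cov, counts = impute_missing_chained(bm, self._cov())
        pd.testing.assert_frame_equal(out.values, bm.values)
        assert counts["biomarker_cells_imputed"] == 0

    def test_collinear_covariate_imputed_exactly(self):
        cov = self._cov()
        cov["double_age"] = 2.0 * cov["age"]
        cov.loc[2, "double_age"] = np.nan
        bm = make_bm(np.arange(1.0, 13.0).reshape(6, 2), log_scale=True)
        _, cov_done, _ = impute_missing_chained(bm, cov)
        assert cov_done.loc[2, "double_age"] == pytest.approx(2.0 * cov.loc[2, "age"])

    def test_mcar_preserves_column_means(self, clean_cohort):
        bm, cov, _ = clean_cohort
        lbm = log_transform(bm)
        rng = np.random.default_rng(8)
        vals = lbm.values.to_numpy().copy()
        miss = rng.random(vals.shape) < 0.05
        vals[miss] = np.nan
        holey = make_bm(pd.DataFrame(vals, columns=lbm.values.columns),
                        missing=miss, log_scale=True)
        out, _, _ = impute_missing_chained(holey, cov)
        full_means = lbm.values.mean()
        imputed_means = out.values.mean()
        se = lbm.values.std() / np.sqrt(len(lbm.values))
        assert (np.abs(imputed_means - full_means) < 2 * se).all()

    def test_fully_missing_variable_rejected(self):
        cov = self._cov()
        cov["bad"] = np.nan
        bm = make_bm(np.ones((6, 1)), log_scale=True)
        with pytest.raises(DataError):
            impute_missing_chained(bm, cov)


class TestDilutionStandardisation:
    def test_divide_arithmetic(self):
        bm = make_bm(np.array([[10.0]]), matrix="urine")
        cov = pd.DataFrame({"creatinine": [0.5]})
        out = standardize_dilution(bm, cov, "divide")
        assert out.values.iloc[0, 0] == pytest.approx(20.0)  # ug/g creatinine

    def test_non_lipid_blood_biomarker_never_altered(self):
        bm = make_bm(np.array([[10.0]]), matrix="blood")
        cov = pd.DataFrame({"creatinine": [0.5], "blood_lipids": [6.0]})
        for mode in ("divide", "covariate", "none"):
            out = standardize_dilution(bm, cov, mode)
            assert out.values.iloc[0, 0] == 10.0

    def test_lipid_soluble_blood_divided_by_lipids(self):
        bm = make_bm(np.array([[12.0]]), matrix="blood", lipid_soluble=True)
        cov = pd.DataFrame({"blood_lipids": [6.0]})
        out = standardize_dilution(bm, cov, "divide")
        assert out.values.iloc[0, 0] == pytest.approx(2.0)

    def test_bad_creatinine_lists_subjects(self):
        bm = make_bm(np.array([[1.0], [1.0]]), matrix="urine")
        cov = pd.DataFrame({"creatinine": [1.0, -0.2]})
        with pytest.raises(DataError, match="creatinine"):
            standardize_dilution(bm, cov, "divide")


class TestResidualisation:
    def test_empty_list_mean_centres(self):
        vals = pd.DataFrame({"b": [1.0, 2.0, 3.0]})
        out = residualize_covariates(vals, pd.DataFrame(index=vals.index), [])
        assert np.allclose(out["b"], [-1, 0, 1])

    def test_exact_linear_dependence_gives_zero_residuals(self):
        cov = pd.DataFrame({"age": [20.0, 30, 40, 50]})
        vals = pd.DataFrame({"b": 2.0 * cov["age"]})
        out = residualize_covariates(vals, cov, ["age"])
        assert np.abs(out["b"]).max() < 1e-10

    def test_orthogonality_after_planted_effect(self, clean_cohort):
        bm, cov, _ = clean_cohort
        lbm = log_transform(bm)
        resid = residualize_covariates(lbm.values, cov, ["age", "bmi", "smoking"])
        for c in ("age", "bmi", "smoking"):
            x = cov[c] - cov[c].mean()
            corr = resid.apply(lambda col: np.corrcoef(col, x)[0, 1])
            assert np.abs(corr).max() < 1e-10

    def test_collinear_design_named(self):
        cov = pd.DataFrame({"age": [1.0, 2, 3], "age2": [2.0, 4, 6]})
        vals = pd.DataFrame({"b": [1.0, 2, 1]})
        with pytest.raises(DataError, match="age2"):
            residualize_covariates(vals, cov, ["age", "age2"])


class TestScaling:
    def test_simple_column(self):
        out = zscore_scale(pd.DataFrame({"b": [1.0, 2.0, 3.0]}))
        assert np.allclose(out.values["b"], [-1, 0, 1])

    def test_standardised_column_unchanged(self):
        col = pd.Series([-1.0, 0.0, 1.0], name="b")
        out = zscore_scale(col.to_frame())
        assert np.allclose(out.values["b"], col)

    def test_column_norms_are_sqrt_n_minus_1(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.gamma(2, 2, size=(40, 4)))
        df.columns = df.columns.astype(str)
        out = zscore_scale(df)
        norms = np.linalg.norm(out.to_numpy(), axis=0)
        assert np.allclose(norms, np.sqrt(39))

    def test_zero_variance_named(self):
        with pytest.raises(DataError, match="flat"):
            zscore_scale(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestSingleBiomarkerSelection:
    def _bm(self):
        bm = make_bm(np.ones((3, 4)) * 2.0)
        bm.meta["substance"] = ["arsenic", "arsenic", "arsenic", "lead"]
        return bm

    def test_empty_mapping_is_identity(self):
        bm = self._bm()
        out, dropped = select_single_biomarker(bm, {})
        assert out.biomarkers == bm.biomarkers and dropped == []

    def test_species_dropped_per_mapping(self):
        out, dropped = select_single_biomarker(self._bm(), {"arsenic": "0"})
        assert out.biomarkers == ["0", "3"]
        assert sorted(dropped) == ["1", "2"]

    def test_unknown_biomarker_rejected(self):
        with pytest.raises(DataError):
            select_single_biomarker(self._bm(), {"arsenic": "nope"})


class TestFullChain:
    def test_processed_matrix_is_standardised(self, small_cohort):
        bm, cov, _ = small_cohort
        pm, report = preprocess(bm, cov)
        vals = pm.values
        assert np.abs(vals.mean()).max() < 1e-12
        assert np.allclose(vals.std(ddof=1), 1.0)
        assert not vals.isna().any().any()
        steps = [p["step"] for p in pm.provenance]
        assert steps == [
            "select_single_biomarker", "filter_by_censoring",
            "standardize_dilution", "log_transform", "impute_censored_ml",
            "impute_missing_chained", "residualize_covariates", "zscore_scale",
        ]

    def test_rerun_is_byte_identical(self, small_cohort):
        bm, cov, _ = small_cohort
        pm1, _ = preprocess(bm, cov, seed=5)
        pm2, _ = preprocess(bm, cov, seed=5)
        pd.testing.assert_frame_equal(pm1.values, pm2.values)
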