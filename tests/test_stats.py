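"""Group tests, robust regressions, FDR, and the mixed model."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import alphapeak as ap
from conftest import make_metadata, make_region_table


class TestTwoSampleT:
    def test_age_summaries_reproduce_reported_t(self):
        t, df, p = ap.two_sample_t(19, 72.5, 7.5, 24, 69.6, 9.0)
        assert df == 41
        assert t == pytest.approx(-1.127, abs=1e-3)
        assert p == pytest.approx(0.266, abs=5e-3)

    def test_identical_summaries_give_zero(self):
        t, _, p = ap.two_sample_t(10, 5.0, 1.0, 12, 5.0, 1.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_srs_summaries_close_to_reported(self):
        t, _, _ = ap.two_sample_t(19, 67.6, 14.3, 24, 46.4, 6.4)
        assert abs(t - (-6.493)) < 0.05

    def test_matches_scipy_on_raw_vectors(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, 15), rng.normal(0.5, 1.2, 20)
        t, df, p = ap.two_sample_t_from_samples(x1, x2)
        ref = sps.ttest_ind(x2, x1, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_flags_infinite_t(self):
        t, _, _ = ap.two_sample_t(5, 1.0, 0.0, 5, 2.0, 0.0)
        assert np.isinf(t)


class TestChiSquare:
    def test_sex_table_uncorrected(self):
        chi2, df, p = ap.chi_square_2x2(13, 6, 14, 10, continuity=False)
        assert df == 1
        assert round(chi2, 3) == 0.462
        assert p == pytest.approx(0.497, abs=5e-3)

    def test_validity_table_with_yates(self):
        chi2, _, p = ap.chi_square_2x2(1227, 65, 1599, 33, continuity=True)
        assert round(chi2, 1) == 19.2
        assert p < 0.001

    def test_equal_proportions_give_zero(self):
        chi2, _, _ = ap.chi_square_2x2(10, 10, 10, 10, continuity=False)
        assert chi2 == pytest.approx(0.0)

    def test_cross_product_formula_identity(self):
        a, b, c, d = 13, 6, 14, 10
        n = a + b + c + d
        ref = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        chi2, _, _ = ap.chi_square_2x2(a, b, c, d, continuity=False)
        assert chi2 == pytest.approx(ref, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ap.chi_square_2x2(0, 0, 5, 5)

    def test_rxc_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        table = rng.integers(5, 50, size=(10, 2)).astype(float)
        table[3, 0] += 40  # one shifted row
        chi2, df, _ = ap.chi_square_rxc(table)
        assert df == 9
        expected = (table.sum(axis=1)[:, None]
                    * table.sum(axis=0)[None, :] / table.sum())
        ref = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(ref, abs=1e-10)

    def test_rxc_reduces_to_2x2(self):
        chi2a, _, _ = ap.chi_square_rxc(np.array([[13, 6], [14, 10]]))
        chi2b, _, _ = ap.chi_square_2x2(13, 6, 14, 10, continuity=False)
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_identical_row_proportions_give_zero(self):
        table = np.outer([10, 20, 30], [0.3, 0.7]) * 10
        chi2, _, _ = ap.chi_square_rxc(table)
        assert chi2 == pytest.approx(0.0, abs=1e-10)


class TestOlsRobust:
    def test_noiseless_line_is_exact(self):
        x = np.linspace(0, 1, 30)
        res = ap.fit_ols_robust(2 + 3 * x, pd.DataFrame({"x": x}))
        assert res["intercept"]["coef"] == pytest.approx(2.0, abs=1e-10)
        assert res["x"]["coef"] == pytest.approx(3.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0)

    def test_robust_and_classical_share_point_estimates(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 40)
        y = 1 + 2 * x + rng.normal(0, 1 + x)
        X = pd.DataFrame({"x": x})
        hc1 = ap.fit_ols_robust(y, X, se_flavor="HC1")
        cls = ap.fit_ols_robust(y, X, se_flavor="nonrobust")
        np.testing.assert_allclose(hc1.coef, cls.coef, atol=1e-12)
        assert not np.allclose(hc1.se, cls.se)

    def test_interaction_model_residual_df(self):
        cfg, meta = make_metadata(19, 24, seed=1)
        rng = np.random.default_rng(1)
        table = make_region_table(cfg, meta, rng)
        scan = ap.region_interaction_scan(table, meta)
        for res in scan.results.values():
            assert res.df_resid == 39  # 43 - 4 terms

    def test_affine_invariance_of_t_statistics(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(50, 90, 43)
        y = 9 + 0.02 * x + rng.normal(0, 0.4, 43)
        raw = ap.fit_ols_robust(y, pd.DataFrame({"x": x}))
        std = ap.fit_ols_robust(y, pd.DataFrame({"x": (x - x.mean()) / x.std()}))
        assert raw["x"]["t"] == pytest.approx(std["x"]["t"], abs=1e-8)

    def test_collinear_design_names_terms(self):
        x = np.linspace(0, 1, 20)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2|x"):
            ap.fit_ols_robust(np.ones(20), X)

    def test_ci_equals_coef_plus_minus_critical_se(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 30)
        y = 1 + x + rng.normal(0, 0.5, 30)
        res = ap.fit_ols_robust(y, pd.DataFrame({"x": x}))
        crit = sps.t.ppf(0.975, res.df_resid)
        cell = res["x"]
        assert cell["ci"][0] == pytest.approx(cell["coef"] - crit * cell["se"],
                                              abs=1e-8)


class TestBhFdr:
    def test_single_small_p_rejected(self):
        d = ap.bh_fdr([0.04])
        assert d.reject.tolist() == [True]

    def test_all_ones_rejected_nothing(self):
        d = ap.bh_fdr([1.0] * 8)
        assert not d.reject.any()

    def test_fixed_family_matches_step_up_definition(self):
        fam = [0.001, 0.008, 0.039, 0.041, 0.30, 0.60, 0.74, 0.90, 0.95, 1.0]
        d = ap.bh_fdr(fam, q=0.05)
        m = len(fam)
        ks = [k for k in range(1, m + 1)
              if sorted(fam)[k - 1] <= k * 0.05 / m]
        cutoff = sorted(fam)[max(ks) - 1] if ks else -1.0
        expected = [p <= cutoff for p in fam]
        assert d.reject.tolist() == expected

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=25))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_random_families_match_brute_force(self, fam):
        d = ap.bh_fdr(fam, q=0.05)
        m = len(fam)
        sp = sorted(fam)
        ks = [k for k in range(1, m + 1) if sp[k - 1] <= k * 0.05 / m]
        cutoff = sp[max(ks) - 1] if ks else -1.0
        assert d.reject.tolist() == [p <= cutoff for p in fam]

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        fam = rng.uniform(0, 1, 20)
        d = ap.bh_fdr(fam)
        ref = multipletests(fam, alpha=0.05, method="fdr_bh")[0]
        assert (d.reject == ref).all()

    def test_empty_family(self):
        assert ap.bh_fdr([]).reject.size == 0


class TestRegionScans:
    def test_exact_linear_model_recovered(self):
        cfg, meta = make_metadata(10, 10, seed=6)
        rng = np.random.default_rng(6)
        table = make_region_table(cfg, meta, rng, subject_sd=0.0,
                                  region_sd=0.0,
                                  slopes={("left cingulate", "ASD"): 0.05})
        scan = ap.region_interaction_scan(table, meta)
        res = scan.results["left cingulate"]
        # generator centers age within group, so the raw-age interaction
        # coefficient equals the planted ASD slope exactly
        assert res["diagnosis:age_months"]["coef"] == pytest.approx(0.05,
                                                                    abs=1e-9)

    def test_detects_planted_cingulate_interaction(self):
        # moderate-noise sensitivity condition: the BH family should flag
        # the cingulate regions in nearly every replicate
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg, meta = make_metadata(19, 24, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            table = make_region_table(
                cfg, meta, rng, subject_sd=0.15, region_sd=0.15,
                slopes={("left cingulate", "ASD"): 0.053,
                        ("right cingulate", "ASD"): 0.053})
            scan = ap.region_interaction_scan(table, meta)
            flags = dict(zip(scan.fdr.labels, scan.fdr.reject))
            hits += flags["left cingulate"] and flags["right cingulate"]
        assert hits >= 90

    def test_null_cohort_family_false_flag_rate(self):
        # family-wise P(any BH rejection) under the global null stays at or
        # below the nominal q (plus Monte-Carlo slack)
        false_flags = 0
        n_rep = 2000
        cfg, meta = make_metadata(19, 24, seed=0)
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            table = make_region_table(cfg, meta, rng)
            scan = ap.region_interaction_scan(table, meta)
            false_flags += bool(scan.fdr.reject.any())
        assert false_flags / n_rep <= 0.05 + 0.02

    def test_regions_with_missing_outcome_skipped(self):
        cfg, meta = make_metadata(10, 10, seed=7)
        rng = np.random.default_rng(7)
        table = make_region_table(cfg, meta, rng)
        table.loc[table["region"] == "left frontal", "paf_hz"] = np.nan
        scan = ap.region_interaction_scan(table, meta)
        assert "left frontal" in scan.skipped
        assert len(scan.results) == 9


class TestPerGroupRegression:
    def test_group_dfs_match_design(self):
        cfg, meta = make_metadata(19, 24, seed=8)
        rng = np.random.default_rng(8)
        table = make_region_table(cfg, meta, rng)
        asd = ap.per_group_regression(table, meta, "left cingulate", "ASD")
        td = ap.per_group_regression(table, meta, "left cingulate", "TD")
        assert asd.df_resid == 17  # n=19, 2 terms
        assert td.df_resid == 22   # n=24, 2 terms

    def test_permuted_predictor_rejection_rate(self):
        # permutation null: type-I error of the within-group test
        cfg, meta = make_metadata(19, 24, seed=9)
        rng = np.random.default_rng(9)
        rej = 0
        n_rep = 2000
        for _ in range(n_rep):
            table = make_region_table(cfg, meta, rng)
            meta_perm = meta.copy()
            meta_perm["age_months"] = rng.permutation(
                meta["age_months"].to_numpy())
            res = ap.per_group_regression(table, meta_perm,
                                          "left cingulate", "TD")
            rej += res["age_months"]["p"] < 0.05
        assert abs(rej / n_rep - 0.05) <= 0.02

    def test_constant_predictor_rejected(self):
        cfg, meta = make_metadata(5, 5, seed=10)
        rng = np.random.default_rng(10)
        table = make_region_table(cfg, meta, rng)
        meta2 = meta.copy()
        meta2["age_months"] = 70
        with pytest.raises(ValueError, match="constant"):
            ap.per_group_regression(table, meta2, "left cingulate", "TD")


class TestSubscaleScan:
    def test_five_subscales_give_five_results(self):
        cfg, meta = make_metadata(10, 12, seed=11)
        rng = np.random.default_rng(11)
        table = make_region_table(cfg, meta, rng)
        out = ap.subscale_scan(table, meta)
        assert len(out) == 5
        assert (out["df"] == 10).all()  # 12 TD subjects, 2 terms

    def test_affine_subscale_transform_preserves_t(self):
        cfg, meta = make_metadata(10, 12, seed=12)
        rng = np.random.default_rng(12)
        table = make_region_table(cfg, meta, rng)
        meta2 = meta.copy()
        meta2["srs_cognition"] = 2.0 * meta2["srs_awareness"] - 30.0
        out = ap.subscale_scan(table, meta2)
        t_aw = out.loc[out["subscale"] == "srs_awareness", "t"].iloc[0]
        t_cg = out.loc[out["subscale"] == "srs_cognition", "t"].iloc[0]
        assert t_aw == pytest.approx(t_cg, abs=1e-8)

    def test_constant_subscale_rejected(self):
        cfg, meta = make_metadata(5, 6, seed=13)
        rng = np.random.default_rng(13)
        table = make_region_table(cfg, meta, rng)
        meta2 = meta.copy()
        meta2["srs_motivation"] = 50.0
        with pytest.raises(ValueError, match="constant"):
            ap.subscale_scan(table, meta2)

    def test_missing_column_rejected(self):
        cfg, meta = make_metadata(5, 6, seed=14)
        rng = np.random.default_rng(14)
        table = make_region_table(cfg, meta, rng)
        with pytest.raises(ValueError, match="missing"):
            ap.subscale_scan(table, meta, subscales=("srs_nonexistent",))


class TestMixedModel:
    def test_design_has_twenty_fixed_effects(self):
        cfg, meta = make_metadata(10, 10, seed=15)
        rng = np.random.default_rng(15)
        table = make_region_table(cfg, meta, rng, subject_sd=0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ap.fit_lmm_region_diagnosis(table, meta)
        assert len(res.terms) == 20  # 1 + 9 + 1 + 9

    def test_zero_variance_limit_matches_ols(self):
        import statsmodels.formula.api as smf

        cfg, meta = make_metadata(6, 6, seed=16)
        rng = np.random.default_rng(16)
        table = make_region_table(cfg, meta, rng, subject_sd=0.0,
                                  region_sd=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ap.fit_lmm_region_diagnosis(table, meta)
        df = table.merge(meta, on="subject_id")
        df["diagnosis"] = (df["group"] == "ASD").astype(int)
        ols = smf.ols(
            "paf_hz ~ C(region, Treatment(reference='left cingulate'))"
            " * diagnosis", df).fit()
        np.testing.assert_allclose(res.coef, ols.params.to_numpy(), atol=1e-5)

    def test_recovers_planted_region_offsets(self):
        # balanced toy: known offsets per region, subject SD 0.3
        recovered = 0
        n_rep = 30
        offsets = {r: 0.1 * i for i, r in enumerate(ap.REGIONS)}
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rows, meta_rows = [], []
            for i in range(10):
                sid = f"s{i}"
                g = "ASD" if i < 5 else "TD"
                meta_rows.append({"subject_id": sid, "group": g, "sex": "M",
                                  "age_months": 70})
                u = rng.normal(0, 0.3)
                for r in ap.REGIONS:
                    rows.append({"subject_id": sid, "region": r,
                                 "paf_hz": 9 + offsets[r] + u
                                 + rng.normal(0, 0.1)})
            table = pd.DataFrame(rows)
            meta = pd.DataFrame(meta_rows)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ap.fit_lmm_region_diagnosis(table, meta)
            cell = res["region[left occipital]"]
            truth = offsets["left occipital"]
            recovered += abs(cell["coef"] - truth) <= 2 * cell["se"]
        assert recovered >= 0.85 * n_rep
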