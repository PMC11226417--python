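"""Association battery: cohorts, correlations, contrasts, models, scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plskit import (
    CohortEmptyError,
    analysis_cohort,
    covid_death_model,
    decile_contrast,
    disease_logistic_model,
    lifespan_battery,
    lifespan_correlations,
    lifespan_cox_model,
    lifespan_linear_model,
    single_variant_scan,
    truth_score_definition,
)


def _score_from_truth(phenos, truth, name="pls"):
    return pd.Series(truth.true_score, index=pd.Index(phenos["sample_id"]), name=name)


def _toy_phenos(n=10, adopted=0, alive_fathers=0, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "sex": ["male", "female"] * (n // 2),
            "birth_year": rng.integers(1940, 1968, n),
            "batch": ["b1", "b2"] * (n // 2),
            "center": ["c1"] * n,
            "adopted": [1] * adopted + [0] * (n - adopted),
            "age": rng.integers(40, 70, n),
            "father_age": rng.uniform(60, 90, n),
            "father_alive": [1] * alive_fathers + [0] * (n - alive_fathers),
            "mother_age": rng.uniform(60, 95, n),
            "mother_alive": [0] * n,
        }
    )
    for j in range(5):
        df[f"pc{j + 1}"] = rng.normal(size=n)
    return df


class TestAnalysisCohort:
    def test_all_dead_none_adopted_unchanged(self):
        df = _toy_phenos()
        out = analysis_cohort(df, "father", require_dead=True)
        assert len(out) == len(df)

    def test_hand_count_with_adopted_and_alive(self):
        # adopted participants and alive fathers never overlap here by
        # construction: 10 - 3 adopted - 2 alive = 5
        df = _toy_phenos(n=10, adopted=3)
        df.loc[[5, 6], "father_alive"] = 1
        out = analysis_cohort(df, "father", require_dead=True)
        assert len(out) == 5

    def test_cox_path_keeps_alive_parents(self):
        df = _toy_phenos(n=10, alive_fathers=2)
        out = analysis_cohort(df, "father", require_dead=False)
        assert len(out) == 10
        assert (out["father_alive"] == 1).sum() == 2

    def test_empty_cohort_raises(self):
        df = _toy_phenos(n=4, adopted=4)
        with pytest.raises(CohortEmptyError):
            analysis_cohort(df, "father")


class TestCorrelations:
    def test_affine_transform_gives_unit_pearson(self):
        df = _toy_phenos(n=20)
        s = pd.Series(np.arange(20.0), index=pd.Index(df["sample_id"]), name="s")
        df["father_age"] = 50 + 0.5 * np.arange(20.0)
        pear, spear = lifespan_correlations(s, df, "father")
        assert pear.estimate == pytest.approx(1.0)
        assert spear.estimate == pytest.approx(1.0)

    def test_null_generator_gives_null_correlation(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        rng = np.random.default_rng(99)
        s = pd.Series(rng.normal(size=len(phenos)),
                      index=pd.Index(phenos["sample_id"]), name="noise")
        pear, _ = lifespan_correlations(s, phenos, "father")
        assert abs(pear.estimate) < 3 / np.sqrt(pear.n_used)

    def test_correlation_matches_closed_form_under_generator(self, biobank_nocensor):
        """r = beta * sd(score) / sd(lifespan): Fisher-z 99% band."""
        panel, phenos, truth, cfg = biobank_nocensor
        s = _score_from_truth(phenos, truth)
        pear, _ = lifespan_correlations(s, phenos, "father")
        df = analysis_cohort(phenos, "father")
        sd_life = df["father_age"].std()
        r_theory = cfg.beta_pls * 1.0 / sd_life
        z = np.arctanh(pear.estimate) - np.arctanh(r_theory)
        assert abs(z) < 2.58 / np.sqrt(pear.n_used - 3)


class TestDecileContrast:
    def test_few_valued_score_never_splits_ties(self):
        # a two-level score: each tail is a whole score value
        df = _toy_phenos(n=40)
        vals = np.repeat([0.0, 1.0], 20)
        s = pd.Series(vals, index=pd.Index(df["sample_id"]), name="s")
        res = decile_contrast(s, df, "father", quantile=0.10)
        assert res.n_used == 40  # both whole groups enter

    def test_null_contrast_is_small(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(size=len(phenos)),
                      index=pd.Index(phenos["sample_id"]), name="noise")
        res = decile_contrast(s, phenos, "father")
        assert abs(res.estimate) < 3 * res.se

    def test_signal_contrast_matches_tail_expectation(self, biobank_nocensor):
        """Expected upper-lower gap = 2 * 1.7545 * beta * sd(score)."""
        panel, phenos, truth, cfg = biobank_nocensor
        s = _score_from_truth(phenos, truth)
        res = decile_contrast(s, phenos, "father", quantile=0.10)
        expected = 2 * 1.7545 * cfg.beta_pls
        assert abs(res.estimate - expected) < 3 * res.se


class TestLinearModel:
    def test_permuted_score_is_null(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        rng = np.random.default_rng(8)
        s = pd.Series(rng.permutation(truth.true_score),
                      index=pd.Index(phenos["sample_id"]), name="perm")
        res = lifespan_linear_model(s, phenos, "father", "all", n_pcs=10)
        assert abs(res.estimate) < 3 * res.se

    def test_recovers_generating_slope(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        s = _score_from_truth(phenos, truth)
        res = lifespan_linear_model(s, phenos, "father", "all", n_pcs=10)
        assert abs(res.estimate - cfg.beta_pls) < 3 * res.se

    def test_lifespan_shift_moves_intercept_only(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        s = _score_from_truth(phenos, truth)
        res1 = lifespan_linear_model(s, phenos, "father", "all", n_pcs=10)
        shifted = phenos.copy()
        shifted["father_age"] = shifted["father_age"] + 7.0
        res2 = lifespan_linear_model(s, shifted, "father", "all", n_pcs=10)
        assert res2.estimate == pytest.approx(res1.estimate, abs=1e-10)

    def test_design_contains_prescribed_covariates(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        s = _score_from_truth(phenos, truth)
        res = lifespan_linear_model(s, phenos, "father", "all", n_pcs=10)
        cols = res.design_columns
        assert "birth_year" in cols
        assert sum(c.startswith("pc") for c in cols) == 10
        assert any(c.startswith("batch_") for c in cols)
        assert any(c.startswith("center_") for c in cols)


class TestCoxModel:
    def test_protective_score_has_hr_below_one(self, biobank_small):
        panel, phenos, truth, cfg = biobank_small
        s = _score_from_truth(phenos, truth)
        res = lifespan_cox_model(s, phenos, "father", "all", n_pcs=10)
        assert res.estimate < 0
        assert res.ratio < 1

    def test_sign_opposes_linear_beta_without_censoring(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        s = _score_from_truth(phenos, truth)
        lin = lifespan_linear_model(s, phenos, "father", "all", n_pcs=10)
        cox = lifespan_cox_model(s, phenos, "father", "all", n_pcs=10)
        assert np.sign(cox.estimate) == -np.sign(lin.estimate)

    def test_permuted_score_ci_covers_one(self, biobank_small):
        panel, phenos, truth, cfg = biobank_small
        rng = np.random.default_rng(12)
        s = pd.Series(rng.permutation(truth.true_score),
                      index=pd.Index(phenos["sample_id"]), name="perm")
        res = lifespan_cox_model(s, phenos, "father", "all", n_pcs=10)
        lo, hi = res.ratio_ci
        assert lo < 1 < hi


class TestLogisticModels:
    def test_recovers_disease_odds_ratios(self, biobank_small):
        panel, phenos, truth, cfg = biobank_small
        s = _score_from_truth(phenos, truth)
        prs = phenos.set_index("sample_id")["prs_cad"].rename("prs_cad")
        pls_res, prs_res = disease_logistic_model(s, prs, phenos, "cad", n_pcs=10)
        coefs = truth.disease_coefs["cad"]
        assert abs(pls_res.estimate - coefs["log_or_pls"]) < 3 * pls_res.se
        assert abs(prs_res.estimate - coefs["log_or_prs"]) < 3 * prs_res.se

    def test_sex_restricted_disease_has_no_sex_column(self, biobank_small):
        panel, phenos, truth, cfg = biobank_small
        s = _score_from_truth(phenos, truth)
        prs = phenos.set_index("sample_id")["prs_breast_cancer"]
        pls_res, _ = disease_logistic_model(s, prs, phenos, "breast_cancer", n_pcs=10)
        assert "sex_male" not in pls_res.design_columns
        # mixed-sex disease keeps the sex column
        prs2 = phenos.set_index("sample_id")["prs_cad"]
        pls2, _ = disease_logistic_model(s, prs2, phenos, "cad", n_pcs=10)
        assert "sex_male" in pls2.design_columns

    def test_covid_model_restricted_to_infected(self, biobank_small):
        panel, phenos, truth, cfg = biobank_small
        s = _score_from_truth(phenos, truth)
        res = covid_death_model(s, phenos, n_pcs=5)
        assert res.n_used == int((phenos["covid_infected"] == 1).sum())
        assert res.n_used < len(phenos)
        assert "sex_male" in res.design_columns
        assert not any(c.startswith("batch") for c in res.design_columns)


class TestSingleVariantScan:
    def test_scan_is_complete_and_flags_monomorphic(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        sub = panel.subset_variants(range(30))
        sub.dosages[:, 0] = 1.0  # force monomorphic
        results = single_variant_scan(sub, phenos, "father", "all", n_pcs=5)
        assert len(results) == 30
        assert results[0].note == "monomorphic" and np.isnan(results[0].estimate)
        assert [r.term for r in results] == list(sub.variants["variant_id"])
        cols = results[1].design_columns
        assert sum(c.startswith("pc") for c in cols) == 5
        assert not any(c.startswith("center_") for c in cols)

    def test_causal_effects_recovered_nulls_calibrated(self, biobank_nocensor):
        panel, phenos, truth, cfg = biobank_nocensor
        results = single_variant_scan(panel, phenos, "father", "all", n_pcs=10)
        by_id = {r.term: r for r in results}
        # per-allele effect of causal variant j is beta_pls * w_j / sd(raw score)
        idx = {v: j for j, v in enumerate(panel.variants["variant_id"])}
        causal_cols = [idx[v] for v in truth.causal_variant_ids]
        raw_sd = (np.nan_to_num(panel.dosages[:, causal_cols]) @ truth.causal_weights).std()
        outliers = 0
        for vid, w in zip(truth.causal_variant_ids, truth.causal_weights):
            r = by_id[vid]
            if abs(r.estimate - cfg.beta_pls * w / raw_sd) > 3 * r.se:
                outliers += 1
        assert outliers <= 2  # 3-SE band, 20 causal variants
        w_by_id = set(truth.causal_variant_ids)
        null_p = [r.p_value for r in results
                  if r.term not in w_by_id and not np.isnan(r.p_value)]
        frac = np.mean([p < 0.05 for p in null_p])
        assert 0.0 <= frac < 0.15  # ~5% nominal at this scale

    def test_scan_agrees_with_statsmodels_on_one_variant(self, biobank_nocensor):
        """Cross-check the residualization shortcut against a direct OLS."""
        import statsmodels.api as sm

        panel, phenos, truth, cfg = biobank_nocensor
        sub = panel.subset_variants(range(3))
        results = single_variant_scan(sub, phenos, "father", "all", n_pcs=5)
        df = analysis_cohort(phenos, "father")
        pos = {s: i for i, s in enumerate(panel.samples)}
        rows = [pos[s] for s in df["sample_id"]]
        X = pd.DataFrame({
            "const": 1.0,
            "dosage": np.nan_to_num(sub.dosages[rows, 1]),
            "birth_year": df["birth_year"].to_numpy(dtype=float),
        }, index=df.index)
        X = pd.concat([X, pd.get_dummies(df["batch"], prefix="batch",
                                         drop_first=True, dtype=float),
                       df[[f"pc{i+1}" for i in range(5)]]], axis=1)
        fit = sm.OLS(df["father_age"].to_numpy(), X.astype(float)).fit()
        assert results[1].estimate == pytest.approx(fit.params["dosage"], rel=1e-8)
        assert results[1].se == pytest.approx(fit.bse["dosage"], rel=1e-8)
        assert results[1].p_value == pytest.approx(fit.pvalues["dosage"], rel=1e-6)


class TestBattery:
    def test_all_four_strata_present_per_model(self, biobank_small):
        panel, phenos, truth, cfg = biobank_small
        scores = pd.DataFrame({"pls": truth.true_score},
                              index=pd.Index(phenos["sample_id"]))
        results = lifespan_battery(scores, phenos, n_pcs=5)
        frame = {(r.model, r.stratum) for r in results}
        for model in ("pearson", "spearman", "welch_t", "linear", "coxph"):
            strata = {s for m, s in frame if m == model}
            assert strata == {f"{sex}/{parent}" for sex in ("male", "female")
                              for parent in ("father", "mother")}
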