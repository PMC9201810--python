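"""Contingency statistics, GLMM battery and ROC machinery."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from quadseg import (
    TwoByTwo,
    analyze_cohort,
    cmh_analysis,
    default_config_from_paper,
    fit_binary_glmm,
    fit_multinomial_glmm,
    odds_ratio,
    roc_evaluate,
    select_covariates,
    simulate_cohort,
    tabulate_modes,
)
from quadseg.glmm import GLMMError
from quadseg.pipeline import classified_table_from_simulation
from quadseg.stats import CohortError, UndefinedOddsRatio, glmm_scores, pool_modes


def make_cohort(rng, n_carriers=60, n_embryos=5, beta_sex=0.0, sigma=0.0):
    """Small logistic cohort with a binary sex covariate."""
    rows = []
    for i in range(n_carriers):
        sex = "female" if rng.random() < 0.5 else "male"
        u = rng.normal(0, sigma)
        for j in range(n_embryos):
            eta = 0.2 + beta_sex * (sex == "female") + u
            unb = rng.random() < 1 / (1 + np.exp(-eta))
            rows.append(
                {
                    "carrier_id": f"C{i}",
                    "sex": sex,
                    "acr_involved": bool(i % 2),
                    "tar1": rng.uniform(0.1, 0.9),
                    "age": 30.0,
                    "mode": "adjacent-1" if unb else "alternate",
                }
            )
    return pd.DataFrame(rows)


class TestTabulateModes:
    def test_single_mode_cohort(self):
        df = pd.DataFrame({"mode": ["adjacent-1"] * 7})
        t = tabulate_modes(df)
        assert t.loc["adjacent-1", "percent"] == 100.0
        assert t.loc["2:2", "count"] == 7

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"mode": rng.choice(["alternate", "adjacent-1", "3:1", "ND"], 500)}
        )
        t = tabulate_modes(df)
        body = t.loc[["alternate", "adjacent-1", "adjacent-2", "3:1", "4:0/other"]]
        assert body["percent"].sum() == pytest.approx(100.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortError):
            tabulate_modes(pd.DataFrame({"mode": []}))

    def test_simulated_proportions_match_generator(self, chrom_table):
        """Observed mode frequencies track the generating multinomial within
        3 Monte-Carlo standard errors (null effects, no clustering)."""
        cfg = default_config_from_paper(effects="null", seed=11, n_carriers=2200)
        cfg.random_intercept_sd = 0.0
        sim = simulate_cohort(cfg)
        tab = classified_table_from_simulation(sim, chrom_table)
        t = tabulate_modes(tab)
        n = len(tab)
        expected = {
            "alternate": 46.1, "adjacent-1": 31.3,
            "adjacent-2": 12.4, "3:1": 5.4, "4:0/other": 4.7,
        }
        for mode, pct in expected.items():
            se = 100 * np.sqrt(pct / 100 * (1 - pct / 100) / n)
            assert abs(t.loc[mode, "percent"] - pct) <= 3 * se


class TestOddsRatio:
    def test_symmetric_table(self):
        r = odds_ratio(TwoByTwo(10, 10, 10, 10))
        assert r.or_point == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    def test_haldane_correction_on_zero_cell(self):
        r = odds_ratio(TwoByTwo(5, 0, 3, 7))
        assert np.isfinite(r.or_point) and r.or_point > 1

    def test_degenerate_margin_undefined(self):
        with pytest.raises(UndefinedOddsRatio):
            odds_ratio(TwoByTwo(0, 0, 3, 7))


def mantel_haenszel_oracle(strata):
    """Textbook MH common OR: sum(ad/n) / sum(bc/n)."""
    num = sum(t.a * t.d / t.total for t in strata)
    den = sum(t.b * t.c / t.total for t in strata)
    return num / den


class TestCMH:
    def test_identical_balanced_strata(self):
        strata = [TwoByTwo(10, 10, 10, 10)] * 2
        r = cmh_analysis(strata)
        assert r.common_or == pytest.approx(1.0)
        assert r.homogeneity_p == pytest.approx(1.0, abs=1e-6)

    def test_common_or_matches_textbook_formula(self):
        # the published stratification: sex as exposure within
        # with/without-acrocentric strata
        strata = [TwoByTwo(1334, 816, 891, 851), TwoByTwo(2069, 1776, 1547, 1562)]
        r = cmh_analysis(strata)
        assert r.common_or == pytest.approx(mantel_haenszel_oracle(strata), abs=1e-6)

    def test_common_or_between_stratum_ors(self):
        strata = [TwoByTwo(120, 80, 90, 110), TwoByTwo(200, 150, 160, 190)]
        ors = sorted(odds_ratio(t).or_point for t in strata)
        r = cmh_analysis(strata)
        assert ors[0] <= r.common_or <= ors[1]

    def test_opposite_effects_fail_homogeneity(self):
        # OR 2 and OR 0.5 by construction, 1000 per stratum
        strata = [TwoByTwo(400, 200, 200, 200), TwoByTwo(200, 400, 200, 200)]
        r = cmh_analysis(strata)
        assert r.homogeneity_p < 0.05

    def test_single_stratum_degenerates_to_plain_or(self):
        t = TwoByTwo(30, 20, 25, 25)
        r = cmh_analysis([t])
        assert r.common_or == pytest.approx(odds_ratio(t).or_point)


class TestBinaryGLMM:
    def test_reduces_to_logistic_without_clustering(self):
        """With zero true random-effect variance the GLMM coefficients
        match plain logistic regression within 2 SE and sigma-hat ~ 0."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        df = make_cohort(rng, n_carriers=150, beta_sex=0.5, sigma=0.0)
        fit = fit_binary_glmm(df, ["sex"])
        X = np.column_stack(
            [np.ones(len(df)), (df["sex"] == "female").to_numpy(float)]
        )
        y = (df["mode"] != "alternate").to_numpy(int)
        ref = sm.Logit(y, X).fit(disp=0)
        for j, term in enumerate(["intercept", "sex_female"]):
            est = fit.coefficients.loc[term]
            assert abs(est["coef"] - ref.params[j]) < 2 * est["se"]
        assert fit.random_intercept_sd < 0.15

    def test_loglik_dominates_null(self):
        rng = np.random.default_rng(7)
        df = make_cohort(rng, beta_sex=0.8, sigma=0.4)
        fit = fit_binary_glmm(df, ["sex"])
        assert fit.loglik >= fit.loglik_null - 1e-6

    def test_constant_covariate_named_in_error(self):
        rng = np.random.default_rng(1)
        df = make_cohort(rng)
        df["tar1"] = 0.5
        with pytest.raises(GLMMError, match="tar1"):
            fit_binary_glmm(df, ["tar1"])

    def test_fewer_than_two_carriers_rejected(self):
        df = pd.DataFrame(
            {"carrier_id": ["C0"] * 4, "sex": ["female"] * 4,
             "mode": ["alternate", "adjacent-1"] * 2}
        )
        with pytest.raises(CohortError):
            fit_binary_glmm(df, ["sex"])

    def test_agrees_with_lme4(self, tmp_path, chrom_table):
        """Cross-check the quadrature ML fit against glmer (nAGQ=25)."""
        cfg = default_config_from_paper(seed=3, n_carriers=250)
        sim = simulate_cohort(cfg)
        tab = classified_table_from_simulation(sim, chrom_table)
        fit = fit_binary_glmm(tab, ["sex", "acr_involved", "tar1"])
        csv = tmp_path / "cohort.csv"
        pd.DataFrame(
            {
                "carrier_id": tab["carrier_id"],
                "female": (tab["sex"] == "female").astype(int),
                "acr": tab["acr_involved"].astype(int),
                "tar1": tab["tar1"],
                "y": (tab["mode"] != "alternate").astype(int),
            }
        ).to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ female + acr + tar1 + (1|carrier_id),
                       data=d, family=binomial, nAGQ=25)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.strip().splitlines()]
        ours = [
            fit.coefficients.loc[t, "coef"]
            for t in ("intercept", "sex_female", "acr_involved", "tar1")
        ] + [fit.random_intercept_sd]
        assert ours == pytest.approx(vals, abs=2e-3)


class TestSelectCovariates:
    def test_strong_effect_included_null_excluded(self):
        rng = np.random.default_rng(9)
        included, excluded = 0, 0
        for _ in range(5):
            df = make_cohort(rng, n_carriers=400, n_embryos=5, beta_sex=0.4)
            sel, fits = select_covariates(df, ["sex", "age", "tar1"])
            included += "sex" in sel
            excluded += "tar1" not in sel
            assert isinstance(fits["sex"], object)
        assert included == 5      # OR ~1.5 at n=2000: essentially always
        assert excluded >= 4      # null covariate kept out at ~alpha

    def test_degenerate_candidate_does_not_abort_scan(self):
        rng = np.random.default_rng(3)
        df = make_cohort(rng, beta_sex=0.8)
        df["age"] = 30.0  # constant -> per-candidate failure
        sel, fits = select_covariates(df, ["age", "sex"])
        assert isinstance(fits["age"], Exception)
        assert "sex" in sel


class TestMultinomialContrasts:
    def test_all_alternate_cohort_skips_every_contrast(self):
        df = pd.DataFrame(
            {
                "carrier_id": [f"C{i}" for i in range(20)] * 2,
                "sex": ["female", "male"] * 20,
                "mode": ["alternate"] * 40,
            }
        )
        assert fit_multinomial_glmm(df, covariates=["sex"]) == {}

    def test_contrast_fits_mirror_mode_layout(self, chrom_table):
        cfg = default_config_from_paper(seed=21, n_carriers=400)
        sim = simulate_cohort(cfg)
        tab = classified_table_from_simulation(sim, chrom_table)
        fits = fit_multinomial_glmm(tab, covariates=["sex", "acr_involved", "tar1"])
        assert set(fits) <= {"adjacent-1", "adjacent-2", "3:1", "4:0/other"}
        assert "adjacent-1" in fits
        f = fits["adjacent-1"]
        assert f.outcome == "adjacent-1 vs alternate"
        assert f.n_obs == int((pool_modes(tab["mode"]).isin(["alternate", "adjacent-1"])).sum())


class TestROC:
    def test_perfect_separation(self):
        r = roc_evaluate(np.r_[np.zeros(50), np.ones(50)], np.r_[np.zeros(50), np.ones(50)])
        assert r.auc == pytest.approx(1.0)
        assert r.sensitivity == pytest.approx(1.0)
        assert r.specificity == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, size=10_000)
        assert roc_evaluate(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_pairwise_exceedance(self):
        """AUC equals the probability that a random positive outranks a
        random negative (brute-force pairwise count, ties = 1/2)."""
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200).round(1)  # rounding forces ties
        labels = (rng.random(200) < 0.4).astype(int)
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        assert roc_evaluate(scores, labels).auc == pytest.approx(
            pairs / (len(pos) * len(neg))
        )

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            roc_evaluate(np.arange(5.0), np.ones(5, dtype=int))


class TestAnalyzeCohort:
    def test_full_battery_runs(self, chrom_table):
        cfg = default_config_from_paper(seed=31, n_carriers=300)
        sim = simulate_cohort(cfg)
        tab = classified_table_from_simulation(sim, chrom_table)
        res = analyze_cohort(tab, candidates=("sex", "acr_involved", "tar1", "ts1"))
        assert res["mode_table"].loc["total", "count"] == len(tab)
        assert set(res["cmh"]) == {"sex_within_acr", "acr_within_sex"}
        if res["multivariable"] is not None:
            scores = glmm_scores(res["multivariable"], tab)
            assert len(scores) == len(tab)
            assert res["roc"] is None or 0 <= res["roc"].auc <= 1
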