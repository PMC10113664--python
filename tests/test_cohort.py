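"""Cohort statistics: sample size, eGFR/KDIGO, propensity weighting,
balance diagnostics and effect estimates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phytoscreen.cohort import (
    SampleSizeSpec,
    balance_table,
    chisq_test,
    effect_estimates,
    egfr_ckd_epi,
    iptw_weights,
    kdigo_stage,
    nn_match,
    propensity_scores,
    sample_size_two_proportions,
    standardized_mean_difference,
    ttest_from_summary,
    weighted_logistic_or,
)
from phytoscreen.synthdata import SynthConfig, simulate_cohort


class TestSampleSize:
    def test_published_cohort_value(self):
        spec = SampleSizeSpec(p0=0.71, p1=0.88, z_alpha=1.65, z_beta=1.28)
        assert sample_size_two_proportions(spec) == 95

    def test_larger_gap_needs_fewer_patients(self):
        base = sample_size_two_proportions(SampleSizeSpec(0.71, 0.88, z_alpha=1.65, z_beta=1.28))
        wider = sample_size_two_proportions(SampleSizeSpec(0.61, 0.95, z_alpha=1.65, z_beta=1.28))
        assert wider < base

    def test_formula_evaluation(self):
        spec = SampleSizeSpec(p0=0.5, p1=0.8, z_alpha=1.96, z_beta=1.28)
        assert sample_size_two_proportions(spec) == 51

    def test_exact_quantiles_derived_when_not_given(self):
        spec = SampleSizeSpec(p0=0.71, p1=0.88, alpha=0.05, beta=0.1, sided="one")
        za, zb = spec.quantiles()
        assert za == pytest.approx(stats.norm.isf(0.05))
        assert zb == pytest.approx(stats.norm.isf(0.1))

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(SampleSizeSpec(0.5, 0.5))


class TestEgfrStaging:
    def test_reference_male_value(self):
        # 60-year-old man, creatinine 0.9 mg/dL = 79.56 umol/L
        assert egfr_ckd_epi(0.9 * 88.4, 60, "male") == pytest.approx(92.5, abs=0.1)

    def test_monotone_decreasing_in_creatinine(self):
        vals = [egfr_ckd_epi(s, 60, "male") for s in (50, 80, 120, 300, 600)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_female_path_uses_swapped_constants(self):
        scr, age = 70.0, 55
        scr_mgdl = scr / 88.4
        ratio = scr_mgdl / 0.7
        expected = (
            141 * min(ratio, 1) ** -0.329 * max(ratio, 1) ** -1.209
            * 0.993**age * 1.018
        )
        assert egfr_ckd_epi(scr, age, "female") == pytest.approx(expected)

    def test_vectorized(self):
        out = egfr_ckd_epi(np.array([80.0, 200.0]), np.array([60, 60]), ["male", "male"])
        assert out.shape == (2,)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            egfr_ckd_epi(0.0, 60, "male")

    @pytest.mark.parametrize(
        "egfr,stage",
        [(95, 1), (90, 1), (89.9, 2), (60, 2), (59.9, 3), (30, 3), (29.9, 4),
         (15, 4), (14.9, 5), (0, 5)],
    )
    def test_kdigo_boundaries(self, egfr, stage):
        assert kdigo_stage(egfr) == stage

    def test_staging_partitions_range(self, rng):
        e = rng.random(100) * 150
        s = kdigo_stage(e)
        assert set(np.unique(s)) <= {1, 2, 3, 4, 5}


class TestPropensity:
    def test_single_binary_covariate_saturated_model(self, rng):
        x = rng.integers(0, 2, size=200)
        t = (rng.random(200) < np.where(x == 1, 0.7, 0.3)).astype(int)
        frame = pd.DataFrame({"x": x, "treated": t})
        p = propensity_scores(frame, ["x"])
        for stratum in (0, 1):
            assert p[x == stratum].mean() == pytest.approx(
                t[x == stratum].mean(), abs=1e-6
            )

    def test_null_covariates_give_prevalence(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(
                {"x": rng.normal(size=150), "treated": rng.integers(0, 2, 150)}
            )
            p = propensity_scores(frame, ["x"])
            from phytoscreen.screen import roc_auc

            aucs.append(roc_auc(frame["treated"].to_numpy(), p).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_perfect_separation_raises(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
                              "treated": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(ValueError):
            propensity_scores(frame, ["x"])


class TestIPTW:
    def test_half_scores_unstabilized(self):
        w = iptw_weights(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0], bool),
                         stabilized=False)
        assert np.allclose(w, 2.0)

    def test_stabilized_weights_mean_one_per_arm(self, rng):
        p = np.clip(rng.random(400), 0.05, 0.95)
        t = rng.random(400) < p
        w = iptw_weights(p, t, stabilized=True, truncate_pct=None)
        assert w[t].mean() == pytest.approx(1.0, abs=0.15)
        assert w[~t].mean() == pytest.approx(1.0, abs=0.15)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            iptw_weights(np.array([0.0, 0.5]), np.array([True, False]))

    def test_weighting_balances_planted_confounders(self):
        """Post-weighting SMD < 0.1 for every confounder on the synthetic
        confounded cohort."""
        cfg = SynthConfig()
        ok = 0
        for seed in range(20):
            frame = simulate_cohort(cfg, seed=seed)
            frame["log_scr"] = np.log(frame["scr"])
            covs = ["age", "sex_male", "stay_days", "log_scr"]
            p = propensity_scores(frame, covs)
            w = iptw_weights(p, frame["treated"].to_numpy(bool))
            bal = balance_table(frame, covs, weights=w)
            ok += bal["smd_after"].max() < 0.1
        assert ok >= 18


class TestMatching:
    def test_identical_arms_pair_perfectly(self):
        p = np.concatenate([np.linspace(0.2, 0.8, 10)] * 2)
        t = np.repeat([True, False], 10)
        pairs = nn_match(p, t)
        assert len(pairs) == 10
        for i, j in pairs:
            assert p[i] == pytest.approx(p[j])

    def test_zero_caliper_keeps_exact_pairs_only(self):
        p = np.array([0.3, 0.5, 0.3, 0.6])
        t = np.array([True, True, False, False])
        pairs = nn_match(p, t, caliper=0.0)
        assert pairs == [(0, 2)]

    def test_cohort_sized_like_study_yields_91_pairs(self):
        frame = simulate_cohort(SynthConfig(), seed=0)
        frame["log_scr"] = np.log(frame["scr"])
        p = propensity_scores(frame, ["age", "sex_male", "stay_days", "log_scr"])
        pairs = nn_match(p, frame["treated"].to_numpy(bool))
        assert len(pairs) >= 91


class TestSMD:
    def test_identical_distributions_zero(self):
        x = np.arange(10.0)
        assert standardized_mean_difference(x, x) == 0.0

    def test_unit_gap_unit_sd(self, rng):
        # |1 - 0| / sqrt((1 + 1) / 2) = 1
        xt = rng.normal(1, 1, 20000)
        xc = rng.normal(0, 1, 20000)
        assert standardized_mean_difference(xt, xc) == pytest.approx(1.0, abs=0.02)

    def test_weighting_toward_balance_reduces_smd(self):
        xt = np.array([2.0, 2.0, 2.0, 0.0])
        xc = np.array([0.0, 0.0, 0.0, 2.0])
        before = standardized_mean_difference(xt, xc)
        # upweight each arm's minority value so the weighted means meet
        wt = np.array([1.0, 1.0, 1.0, 3.0])
        wc = np.array([1.0, 1.0, 1.0, 3.0])
        after = standardized_mean_difference(xt, xc, wt, wc)
        assert after < before


class TestSummaryTests:
    def test_equal_means_null(self):
        t, df, p = ttest_from_summary(5, 1, 20, 5, 1, 20)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_age_row(self):
        # printed summaries reproduce the reported p up to rounding
        _, _, p = ttest_from_summary(62.35, 17.67, 91, 62.52, 17.16, 91)
        assert p == pytest.approx(0.9476, abs=0.002)

    def test_closed_form_t_cdf(self):
        t, df, p = ttest_from_summary(10, 2, 16, 8, 2, 16)
        tt = (10 - 8) / (2 * np.sqrt(2 / 16))
        assert t == pytest.approx(tt)
        assert p == pytest.approx(2 * stats.t.sf(tt, 30), abs=1e-12)

    def test_published_sex_table(self):
        chi2, df, p = chisq_test([[56, 35], [58, 33]], yates=True)
        assert df == 1
        assert p == pytest.approx(0.878, abs=1e-3)

    def test_published_ckd_stage_table(self):
        chi2, df, p = chisq_test(
            [[14, 28, 23, 20, 6], [14, 20, 32, 16, 9]], yates=False
        )
        assert df == 4
        assert chi2 == pytest.approx(3.851, abs=1e-3)
        assert p == pytest.approx(0.427, abs=1e-3)

    def test_df4_p_matches_closed_form(self):
        chi2, df, p = chisq_test([[14, 28, 23, 20, 6], [14, 20, 32, 16, 9]])
        # chi-square survival with df=4: e^{-x/2} (1 + x/2)
        assert p == pytest.approx(np.exp(-chi2 / 2) * (1 + chi2 / 2), abs=1e-10)

    def test_identical_rows_null(self):
        chi2, _, p = chisq_test([[10, 20], [10, 20]], yates=False)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_yates_clamps_at_zero(self):
        # |O-E| < 0.5 everywhere: corrected statistic must clamp to 0
        chi2, _, p = chisq_test([[10, 10], [10, 11]], yates=True)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_test([[0, 0], [5, 5]])


class TestEffectEstimates:
    def test_rr_and_or(self):
        est = effect_estimates([[30, 70], [20, 80]])
        assert est["rr"] == pytest.approx(1.5)
        assert est["or"] == pytest.approx(30 * 80 / (70 * 20))

    def test_symmetric_table_null(self):
        est = effect_estimates([[25, 25], [25, 25]])
        assert est["rr"] == 1.0 and est["or"] == 1.0

    def test_ci_shrinks_with_sample_size(self):
        small = effect_estimates([[30, 70], [20, 80]])
        big = effect_estimates([[300, 700], [200, 800]])
        assert (big["or_ci"][1] - big["or_ci"][0]) < (
            small["or_ci"][1] - small["or_ci"][0]
        )

    def test_zero_cell_haldane_flagged(self):
        est = effect_estimates([[10, 0], [5, 5]])
        assert est["haldane_corrected"]


class TestPlantedEffectRecovery:
    def test_iptw_debiases_the_planted_effect(self):
        """The naive OR is biased up by confounding; IPTW pulls the
        estimate back toward the planted value."""
        cfg = SynthConfig(treatment_or=2.5)
        iptw_or, naive_or = [], []
        for seed in range(20):
            frame = simulate_cohort(cfg, seed=seed)
            frame["log_scr"] = np.log(frame["scr"])
            covs = ["age", "sex_male", "stay_days", "log_scr"]
            p = propensity_scores(frame, covs)
            w = iptw_weights(p, frame["treated"].to_numpy(bool))
            iptw_or.append(
                weighted_logistic_or(frame["improved"], frame["treated"], w)["or"]
            )
            naive_or.append(
                weighted_logistic_or(
                    frame["improved"], frame["treated"], np.ones(len(frame))
                )["or"]
            )
        assert np.median(naive_or) > np.median(iptw_or)  # confounding direction
        assert abs(np.median(iptw_or) - 2.5) < 0.3
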