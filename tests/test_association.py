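"""Tests of the implantation-association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blastomorph.association import (
    PerfectSeparationError,
    analysis_report,
    chi2_test,
    collinearity_screen,
    delong_compare,
    logistic_fit,
    or_from_rates,
    roc_auc,
    split_by_mean,
    two_sample_ttest,
)
from blastomorph.synthetic import CohortGenConfig, generate_cohort

from conftest import auc_pair_count


class TestTTest:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0]
        assert two_sample_ttest(x, x) == (0.0, 1.0)

    def test_hand_computed_pooled_variance(self):
        # means 2 and 5, pooled variance 1, se = sqrt(2/3): t = -3/0.8165
        t, p = two_sample_ttest([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_welch_option_differs_under_variance_imbalance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 5, 40)
        _, p_pooled = two_sample_ttest(x, y)
        _, p_welch = two_sample_ttest(x, y, welch=True)
        assert p_pooled != p_welch

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha=0.05 over 1,000 replicates."""
        rng = np.random.default_rng(123)
        x = rng.normal(size=(1000, 30))
        y = rng.normal(size=(1000, 30))
        _, p = stats.ttest_ind(x, y, axis=1)
        rate = np.mean(p < 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)


class TestChi2:
    def test_independence(self):
        chi2, p = chi2_test([[25, 25], [25, 25]])
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed(self):
        # All expected counts are 20: chi2 = 4 * 100/20 = 20
        chi2, _ = chi2_test([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)

    def test_transpose_invariance(self):
        t = np.array([[12, 30], [25, 9]])
        assert chi2_test(t)[0] == pytest.approx(chi2_test(t.T)[0])

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi2_test([[0, 0], [5, 7]])

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        a = rng.binomial(100, 0.3, size=n_rep)
        b = rng.binomial(100, 0.3, size=n_rep)
        for i in range(n_rep):
            _, p = chi2_test([[a[i], 100 - a[i]], [b[i], 100 - b[i]]])
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = logistic_fit(np.empty((100, 0)), y)
        assert fit["const"].coef == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_single_binary_covariate_matches_cross_product(self):
        # 2x2 table: exposed 40/60 events, unexposed 25/75
        x = np.array([1.0] * 100 + [0.0] * 100)
        y = np.array([1] * 40 + [0] * 60 + [1] * 25 + [0] * 75)
        fit = logistic_fit(x, y, names=["exposed"])
        expected = (40 * 75) / (60 * 25)
        assert fit.odds_ratio("exposed") == pytest.approx(expected, rel=1e-6)
        ci = fit["exposed"]
        assert ci.ci_low <= ci.odds_ratio <= ci.ci_high
        assert ci.odds_ratio == pytest.approx(np.exp(ci.coef))

    def test_parameter_recovery_at_scale(self):
        """Recovered coefficients within 3 Wald SEs of generating values."""
        cfg = CohortGenConfig(
            n_embryos=50_000,
            seed=17,
            beta_size=np.log(1.02),
            beta_age=np.log(0.898),
            beta_icm=np.log(0.987),
            target_prevalence=0.329,
        )
        cohort = generate_cohort(cfg)
        fit = logistic_fit(
            cohort[["icm_size_um", "blastocyst_size_um", "woman_age_years"]],
            cohort["kid"].to_numpy(),
        )
        for name, truth in [
            ("blastocyst_size_um", np.log(1.02)),
            ("woman_age_years", np.log(0.898)),
            ("icm_size_um", np.log(0.987)),
        ]:
            cov = fit[name]
            assert abs(cov.coef - truth) < 3 * cov.se

    def test_separation_detected(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        with pytest.raises(PerfectSeparationError):
            logistic_fit(x, y, names=["x"])

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.arange(10.0), np.ones(10, dtype=int), names=["x"])


class TestOrAndSplit:
    def test_equal_rates_give_unit_or(self):
        assert or_from_rates(0.3, 0.3) == 1.0

    def test_published_rates(self):
        assert or_from_rates(0.412, 0.258) == pytest.approx(2.01, rel=0.005)

    def test_agrees_with_cross_product_on_count_quotients(self):
        # 33/80 vs 21/90
        p1, p2 = 33 / 80, 21 / 90
        cross = (33 * (90 - 21)) / ((80 - 33) * 21)
        assert or_from_rates(p1, p2) == pytest.approx(cross, rel=1e-12)

    def test_boundary_rates_raise(self):
        with pytest.raises(ValueError):
            or_from_rates(0.0, 0.5)
        with pytest.raises(ValueError):
            or_from_rates(0.5, 1.0)

    def test_split_strictly_above_mean(self):
        np.testing.assert_array_equal(
            split_by_mean([140.0, 150.0, 160.0]), [False, False, True]
        )
        assert not split_by_mean([5.0, 5.0, 5.0]).any()

    def test_split_near_half_for_normal_sizes(self):
        rng = np.random.default_rng(3)
        sizes = rng.normal(147, 19.1, 10_000)
        assert split_by_mean(sizes).mean() == pytest.approx(0.5, abs=0.02)


class TestRocAuc:
    def test_perfect_and_all_tied(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]).auc == 1.0
        assert roc_auc([5, 5, 5, 5], [1, 1, 0, 0]).auc == 0.5

    def test_small_concordance_oracle(self):
        assert roc_auc([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0]).auc == pytest.approx(3 / 4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pair_count(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        base = roc_auc(scores, labels)
        for f in (np.exp, lambda s: 3 * s + 2, np.tanh):
            assert roc_auc(f(scores), labels).auc == pytest.approx(base.auc)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(6)
        r = roc_auc(rng.normal(size=80), (rng.random(80) < 0.5).astype(int))
        assert r.ci_low <= r.auc <= r.ci_high

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_delong_se_matches_empirical_sd(self):
        """Mean DeLong SE within 15% of the AUC SD over 500 replicates."""
        rng = np.random.default_rng(99)
        aucs, ses = [], []
        for _ in range(500):
            pos = rng.normal(0.6, 1.0, 60)
            neg = rng.normal(0.0, 1.0, 140)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * 60 + [0] * 140)
            r = roc_auc(scores, labels)
            aucs.append(r.auc)
            ses.append(r.se)
        assert np.mean(ses) == pytest.approx(np.std(aucs, ddof=1), rel=0.15)


class TestDelongCompare:
    def test_score_against_itself(self):
        scores = [0.2, 0.9, 0.4, 0.8]
        labels = [0, 1, 0, 1]
        assert delong_compare(scores, scores, labels) == (0.0, 1.0)

    def test_monotone_transform_gives_p_one(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        z, p = delong_compare(scores, np.exp(scores), labels)
        assert (z, p) == (0.0, 1.0)

    def test_unpaired_lengths_raise(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0], [1.0, 2.0, 3.0], [0, 1])

    def test_agrees_with_bootstrap(self):
        """DeLong p within 0.02 of a 10,000-draw bootstrap of the AUC gap."""
        rng = np.random.default_rng(31)
        n = 40
        labels = np.array([1] * 15 + [0] * 25)
        latent = rng.normal(size=n) + 0.8 * labels
        scores_a = latent + rng.normal(0, 0.5, n)
        scores_b = latent + rng.normal(0, 0.8, n)
        _, p_delong = delong_compare(scores_a, scores_b, labels)

        def auc_of(scores, lab):
            pos = scores[lab == 1]
            neg = scores[lab == 0]
            return (
                (pos[:, None] > neg[None, :]).sum()
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            ) / (len(pos) * len(neg))

        diffs = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.min() == lab.max():
                continue
            diffs.append(auc_of(scores_a[idx], lab) - auc_of(scores_b[idx], lab))
        diffs = np.asarray(diffs)
        z_boot = (auc_of(scores_a, labels) - auc_of(scores_b, labels)) / diffs.std(
            ddof=1
        )
        p_boot = 2 * stats.norm.sf(abs(z_boot))
        assert abs(p_delong - p_boot) < 0.02


class TestCollinearityScreen:
    def test_perfectly_correlated_pair_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "double_x": 2 * x})
        out = collinearity_screen(df)
        assert out["flagged_pairs"][0]["pair"] == ["x", "double_x"]
        assert out["flagged_pairs"][0]["r"] == pytest.approx(1.0)
        assert out["recommended_exclusions"] == ["double_x"]

    def test_independent_covariates_not_flagged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        assert collinearity_screen(df)["flagged_pairs"] == []

    def test_ratio_flagged_against_its_denominator(self):
        cohort = generate_cohort(CohortGenConfig(n_embryos=600, seed=14))
        out = collinearity_screen(cohort[["blastocyst_size_um", "icm_size_um", "icm_ratio"]])
        flagged = {frozenset(f["pair"]) for f in out["flagged_pairs"]}
        assert any("icm_ratio" in pair for pair in flagged)

    def test_constant_covariate_raises(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="constant"):
            collinearity_screen(df)


@pytest.fixture(scope="module")
def null_cohort():
    return generate_cohort(CohortGenConfig(n_embryos=2000, seed=77))


class TestAnalysisReport:
    def test_null_cohort_calibration(self, null_cohort):
        report = analysis_report(null_cohort)
        adj = report["multivariable"]["icm_size_blastocyst_size_age"]["covariates"]
        for name in ("icm_size_um", "blastocyst_size_um", "woman_age_years"):
            cov = adj[name]
            assert cov["ci_low"] <= 1.0 <= cov["ci_high"] or abs(cov["odds_ratio"] - 1) < 0.05
        assert report["roc"]["age_alone"]["auc"] == pytest.approx(0.5, abs=0.05)
        assert report["roc"]["age_plus_criterion"]["auc"] == pytest.approx(0.5, abs=0.05)

    def test_effect_cohort_recovers_mean_split_or(self):
        cfg = CohortGenConfig(
            n_embryos=20_000,
            seed=55,
            beta_size_above_mean=np.log(1.74),
            beta_age=np.log(0.898),
            target_prevalence=0.329,
        )
        report = analysis_report(generate_cohort(cfg))
        got = report["mean_split"]["adjusted"]["covariates"]["size_above_mean"]["odds_ratio"]
        assert got == pytest.approx(1.74, abs=0.10)
        # with a real age effect, the combined model should beat chance
        assert report["roc"]["age_plus_criterion"]["auc"] > 0.55

    def test_report_is_deterministic(self, null_cohort):
        import json

        a = json.dumps(analysis_report(null_cohort), sort_keys=True)
        b = json.dumps(analysis_report(null_cohort), sort_keys=True)
        assert a == b

    def test_rejects_single_outcome_cohort(self, null_cohort):
        bad = null_cohort.assign(kid=0)
        with pytest.raises(ValueError):
            analysis_report(bad)
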