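"""Logistic screening, ROC/AUC with cutoffs, DeLong comparison, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from conftest import brute_force_auc, brute_force_youden

from baepstd.stats import (anova_oneway, compare_aucs, multivariate_stepwise,
                           paired_comparison, roc_analysis,
                           univariate_logistic)


class TestUnivariateLogistic:
    def test_binary_predictor_matches_cross_product_ratio(self):
        """2x2 table a=20, b=10, c=10, d=20: logistic OR equals
        (20*20)/(10*10) = 4."""
        x = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        res = univariate_logistic(x, y)
        assert res.odds_ratio == pytest.approx(4.0, rel=1e-6)
        assert res.ci_low < 4.0 < res.ci_high
        assert res.status == "ok"

    def test_constant_predictor_is_null(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        res = univariate_logistic(np.ones(20), y)
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0
        assert res.status == "degenerate"

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(15), np.zeros(15)]
        x = y * 2.0 - 1.0
        res = univariate_logistic(x, y)
        assert res.status == "separated"

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            univariate_logistic(np.arange(10.0), np.ones(10))

    def test_missing_values_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = (rng.random(60) < sps.norm.cdf(x)).astype(float)
        x_nan = x.copy()
        x_nan[:10] = np.nan
        res = univariate_logistic(x_nan, y)
        ref = univariate_logistic(x[10:], y[10:])
        assert res.n == 50
        assert res.odds_ratio == pytest.approx(ref.odds_ratio, rel=1e-9)


class TestStepwise:
    def _data(self, seed, n=150, n_noise=3):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = (rng.random(n) < sps.norm.cdf(1.5 * x)).astype(float)
        df = pd.DataFrame({"signal": x})
        for k in range(n_noise):
            df[f"noise{k}"] = rng.normal(size=n)
        return df, y

    def test_single_candidate_equals_univariate_refit(self):
        df, y = self._data(1, n_noise=0)
        multi = multivariate_stepwise(df, y)
        uni = univariate_logistic(df["signal"], y, "signal")
        assert len(multi) == 1
        assert multi[0].odds_ratio == pytest.approx(uni.odds_ratio, rel=1e-6)
        assert multi[0].p_value == pytest.approx(uni.p_value, abs=1e-9)

    def test_duplicated_predictor_pruned(self):
        df, y = self._data(2, n_noise=0)
        df["dup"] = df["signal"]
        multi = multivariate_stepwise(df, y)
        assert len(multi) == 1

    def test_signal_survives_noise_eliminated(self):
        """Across 100 seeded replicates the informative variable survives
        backward elimination and pure-noise covariates are eliminated in at
        least 90% of replicates."""
        signal_kept, noise_kept = 0, 0
        reps = 100
        for seed in range(reps):
            df, y = self._data(seed, n=150, n_noise=2)
            kept = {r.variable for r in multivariate_stepwise(df, y)}
            signal_kept += "signal" in kept
            noise_kept += bool(kept - {"signal"})
        assert signal_kept >= 0.95 * reps
        assert noise_kept <= 0.10 * reps

    def test_forward_direction_available(self):
        df, y = self._data(3, n_noise=2)
        multi = multivariate_stepwise(df, y, direction="forward")
        assert any(r.variable == "signal" for r in multi)


class TestROC:
    def test_four_point_example(self):
        """Scores neg {0.1, 0.4}, pos {0.35, 0.8}: 3 of 4 pairs concordant,
        AUC = 0.75."""
        score = [0.1, 0.4, 0.35, 0.8]
        y = [0, 0, 1, 1]
        res = roc_analysis(score, y)
        assert res.auc == pytest.approx(0.75)
        assert res.n_pos == 2 and res.n_neg == 2
        # best J = 0.5 is tied; the higher (more specific) cutoff is reported
        assert res.cutoff == pytest.approx(0.8)
        assert res.sensitivity == pytest.approx(50.0)
        assert res.specificity == pytest.approx(100.0)

    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert 3 < res.cutoff <= 10

    def test_all_ties(self):
        res = roc_analysis(np.ones(10), [0, 1] * 5)
        assert res.auc == pytest.approx(0.5)

    def test_inverted_orientation_reported_as_is(self):
        res = roc_analysis([3, 2, 1, 0], [0, 0, 1, 1])
        assert res.auc == 0.0

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 1)),
                    min_size=4, max_size=50))
    def test_auc_equals_exhaustive_pair_count(self, data):
        """Trapezoidal/rank AUC equals brute-force concordant-pair counting
        (ties half) on every instance."""
        score = np.array([d[0] for d in data], float)
        y = np.array([d[1] for d in data])
        if y.sum() in (0, len(y)):
            return
        res = roc_analysis(score, y)
        assert res.auc == pytest.approx(brute_force_auc(score, y), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 15), st.integers(0, 1)),
                    min_size=6, max_size=40))
    def test_youden_cutoff_matches_brute_force(self, data):
        """The reported cutoff attains the brute-force-maximal J, and the
        reported sens/spec are attained at that cutoff."""
        score = np.array([d[0] for d in data], float)
        y = np.array([d[1] for d in data])
        if y.sum() in (0, len(y)):
            return
        res = roc_analysis(score, y)
        best_j = brute_force_youden(score, y)
        j_at_cutoff = (res.sensitivity + res.specificity) / 100.0 - 1.0
        assert j_at_cutoff == pytest.approx(best_j, abs=1e-9)
        pred = score >= res.cutoff
        sens = 100.0 * (pred & (y == 1)).sum() / (y == 1).sum()
        spec = 100.0 * (~pred & (y == 0)).sum() / (y == 0).sum()
        assert sens == pytest.approx(res.sensitivity, abs=1e-9)
        assert spec == pytest.approx(res.specificity, abs=1e-9)


class TestCompareAUCs:
    def test_identical_scores(self):
        y = [0, 1] * 10
        s = np.arange(20.0)
        assert compare_aucs(s, s, y) == 1.0

    def test_monotone_transform_has_equal_auc(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        assert compare_aucs(s, np.exp(s), y) == 1.0

    def test_informative_vs_noise_has_power(self):
        """Informative vs pure-noise score at n = 200: p < 0.05 in >= 80% of
        seeded replicates."""
        hits, reps = 0, 60
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(100), np.zeros(100)]
            good = y * 1.5 + rng.normal(size=200)
            noise = rng.normal(size=200)
            hits += compare_aucs(good, noise, y) < 0.05
        assert hits >= 0.8 * reps


class TestGroupComparisons:
    def test_identical_paired_samples(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_three_identical_groups(self):
        res = anova_oneway([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        assert res["F"] == pytest.approx(0.0)

    def test_healthy_change_pvalues_uniform_under_null(self):
        """Paired-test p-values on pure-noise pre/post differences are
        uniform on [0, 1] (Kolmogorov-Smirnov check across seeds)."""
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pre = rng.normal(40.0, 5.0, size=15)
            post = pre + rng.normal(0.0, 2.0, size=15)
            pvals.append(paired_comparison(pre, post)["p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
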