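"""Metrics, DeLong AUC machinery, Steiger's dependent-correlation test and
the reference baselines, each checked against brute-force or bootstrap
oracles."""

import math

import numpy as np
import pytest
from scipy.stats import norm, rankdata, spearmanr

from ginscreen.stats import (
    auc_delong,
    baseline_fit,
    confusion_metrics,
    delong_paired_test,
    dependent_correlation_test,
)


def _auc_rank(scores, labels):
    r = rankdata(scores)
    m = int(labels.sum())
    n = len(labels) - m
    return (r[labels == 1].sum() - m * (m + 1) / 2) / (m * n)


class TestConfusionMetrics:
    def test_perfect_separation(self):
        rep = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (1.0, 1.0, 1.0)

    def test_majority_collapse_case(self):
        """All scores below threshold with 1 positive in 100: high accuracy,
        zero sensitivity — the failure mode the resampling ensemble targets."""
        scores = np.full(100, 0.1)
        labels = np.array([1] + [0] * 99)
        rep = confusion_metrics(scores, labels, 0.5)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0
        assert rep.accuracy == 0.99

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        thr = 0.4
        rep = confusion_metrics(scores, labels, thr)
        tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
        fn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 0)
        fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (tn + fp))
        assert rep.accuracy == pytest.approx((tp + tn) / 50)

    def test_single_class_gives_nan_not_zero(self):
        rep = confusion_metrics([0.2, 0.7], [1, 1], 0.5)
        assert math.isnan(rep.specificity) and rep.sensitivity == 0.5

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        reports = [confusion_metrics(scores, labels, t) for t in np.linspace(0, 1, 21)]
        sens = [r.sensitivity for r in reports]
        spec = [r.specificity for r in reports]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))


class TestAucDelong:
    def test_perfect_separation_is_one(self):
        auc, var, ci = auc_delong([0.9, 0.8, 0.1], [1, 1, 0])
        assert auc == 1.0 and ci[1] == 1.0

    def test_null_within_three_se_of_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        auc, var, _ = auc_delong(scores, labels)
        assert abs(auc - 0.5) < 3 * math.sqrt(var)

    def test_equals_exhaustive_pair_counting(self):
        """AUC == concordant pairs (ties 1/2) / (n_pos * n_neg), counted by
        brute-force double loop, on random instances up to n=200."""
        rng = np.random.default_rng(2)
        for n in (12, 63, 200):
            scores = np.round(rng.random(n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            auc, _, _ = auc_delong(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            count = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in pos for y in neg)
            assert auc == pytest.approx(count / (len(pos) * len(neg)), abs=1e-12)

    def test_variance_within_ten_percent_of_bootstrap(self):
        rng = np.random.default_rng(42)
        n = 200
        labels = (rng.random(n) < 0.3).astype(int)
        scores = labels * 0.8 + rng.standard_normal(n)
        _, var, _ = auc_delong(scores, labels)
        boot = []
        for _ in range(10000):
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if 0 < lb.sum() < n:
                boot.append(_auc_rank(scores[idx], lb))
        assert var == pytest.approx(np.var(boot, ddof=1), rel=0.10)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (100, 1000):
            scores = rng.random(n)
            labels = (rng.random(n) < 0.5).astype(int)
            _, _, ci = auc_delong(scores, labels)
            widths.append(ci[1] - ci[0])
        assert widths[1] < widths[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([0.1, 0.2], [1, 1])


class TestDelongPaired:
    def test_identical_scores_give_p_one(self):
        labels = np.array([1, 0, 1, 0, 1, 0])
        scores = np.array([0.8, 0.2, 0.7, 0.3, 0.9, 0.1])
        res = delong_paired_test(scores, scores, labels)
        assert res.difference == 0.0 and res.p == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 40)
        labels[:5] = 1
        labels[5:10] = 0
        a, b = rng.random(40), rng.random(40)
        r1 = delong_paired_test(a, b, labels)
        r2 = delong_paired_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_p_value_matches_bootstrap_oracle(self):
        """Two correlated score vectors on n=60 subjects: the DeLong p agrees
        with a 20,000-rep subject-resampling bootstrap of the AUC difference
        within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        n = 60
        labels = np.array([1] * 20 + [0] * 40)
        sig = labels + rng.standard_normal(n) * 1.2
        a = sig + rng.standard_normal(n) * 0.7
        b = 0.6 * sig + rng.standard_normal(n) * 0.9
        res = delong_paired_test(a, b, labels)
        diffs = []
        for _ in range(20000):
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if 0 < lb.sum() < n:
                diffs.append(_auc_rank(a[idx], lb) - _auc_rank(b[idx], lb))
        p_boot = 2 * norm.sf(abs(res.difference) / np.std(diffs, ddof=1))
        assert res.p == pytest.approx(p_boot, abs=0.03)


class TestDependentCorrelation:
    def test_identical_predictors_give_zero_z(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        c = rng.standard_normal(50)
        res = dependent_correlation_test(x, x, c)
        assert res.z == 0.0 and res.p_two_sided == 1.0

    def test_exact_predictor_strongly_significant(self):
        rng = np.random.default_rng(2)
        crit = rng.standard_normal(100)
        alt = rng.standard_normal(100)
        res = dependent_correlation_test(crit, alt, crit)
        assert res.rho_pred == pytest.approx(1.0)
        assert res.p_two_sided < 1e-6

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        crit = rng.standard_normal(60)
        a = 0.5 * crit + rng.standard_normal(60)
        b = 0.2 * crit + rng.standard_normal(60)
        r1 = dependent_correlation_test(a, b, crit)
        r2 = dependent_correlation_test(b, a, crit)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_p_value_near_bootstrap_oracle(self):
        """Steiger's z on n=40 triples vs a 20,000-rep subject bootstrap of
        the Fisher-z difference of rank correlations. The analytic
        approximation and the bootstrap are expected to agree only to within
        ~0.1 in p at this n; any larger discrepancy would flag a defect."""
        rng = np.random.default_rng(42)
        n = 40
        crit = rng.standard_normal(n)
        pred = 0.7 * crit + rng.standard_normal(n) * 0.8
        alt = 0.3 * crit + rng.standard_normal(n) * 0.9
        res = dependent_correlation_test(pred, alt, crit)
        dz = []
        for _ in range(20000):
            idx = rng.integers(0, n, n)
            r1 = spearmanr(pred[idx], crit[idx]).statistic
            r2 = spearmanr(alt[idx], crit[idx]).statistic
            if abs(r1) < 1 and abs(r2) < 1:
                dz.append(np.arctanh(r1) - np.arctanh(r2))
        obs = np.arctanh(res.rho_pred) - np.arctanh(res.rho_alt)
        p_boot = 2 * norm.sf(abs(obs) / np.std(dz, ddof=1))
        assert res.p_two_sided == pytest.approx(p_boot, abs=0.1)

    def test_listwise_deletion_and_minimum_n(self):
        x = np.arange(20.0)
        c = x + np.random.default_rng(0).standard_normal(20)
        c[:12] = np.nan
        with pytest.raises(ValueError, match="10"):
            dependent_correlation_test(x, x[::-1], c)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dependent_correlation_test(np.ones(20), np.arange(20), np.arange(20.0))


class TestBaselines:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 2.0, -2.0)
        return X, y

    @pytest.mark.parametrize("kind", ["lasso-logistic", "max-margin"])
    def test_separable_data_high_accuracy(self, kind):
        X, y = self._separable()
        scores = baseline_fit(X, y, X, kind, seed=1)
        assert np.mean((scores >= 0.5) == (y == 1)) >= 0.99

    def test_infinite_penalty_zeroes_all_coefficients(self):
        X, y = self._separable()
        scores = baseline_fit(X, y, X, "lasso-logistic", seed=1, C=1e-10)
        assert np.allclose(scores, scores[0])

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            baseline_fit(X, np.zeros(10), X, "lasso-logistic")
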