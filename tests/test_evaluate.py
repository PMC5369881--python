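import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import pcpscore as pcp


def brute_force_auc(pos, neg):
    """Enumerate all (case, control) pairs; ties count half."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_four_point_example(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        roc = pcp.roc_curve(scores, labels)
        assert np.array_equal(roc.thresholds, [np.inf, 5, 4, 3, 1, -np.inf])
        assert np.allclose(roc.sensitivity, [0, 0.5, 0.5, 1, 1, 1])
        assert np.allclose(roc.specificity, [1, 1, 0.5, 0.5, 0, 0])

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.uniform(size=200) < 0.3).astype(int)
        roc = pcp.roc_curve(scores, labels)
        assert roc.sensitivity[0] == 0 and roc.specificity[0] == 1
        assert roc.sensitivity[-1] == 1 and roc.specificity[-1] == 0
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)

    def test_perfect_separation_passes_through_corner(self):
        roc = pcp.roc_curve([1, 2, 8, 9.0], [0, 0, 1, 1])
        assert np.any((roc.sensitivity == 1) & (roc.specificity == 1))

    def test_orientation_identity(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.uniform(size=100) < 0.4).astype(int)
        low = pcp.roc_curve(scores, labels, lower_is_positive=True)
        neg = pcp.roc_curve(-scores, labels)
        assert np.array_equal(low.thresholds, neg.thresholds)
        assert np.array_equal(low.sensitivity, neg.sensitivity)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pcp.roc_curve([1.0, 2.0], [1, 1])


class TestAuc:
    def test_four_point_example(self):
        assert pcp.auc([3, 5, 1, 4.0], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert pcp.auc([2.0] * 10, [1] * 3 + [0] * 7) == pytest.approx(0.5)

    def test_reflection_identity(self, rng):
        scores = np.round(rng.normal(size=300), 1)  # induce ties
        labels = (rng.uniform(size=300) < 0.25).astype(int)
        assert pcp.auc(scores, labels) + pcp.auc(-scores, labels) == pytest.approx(1.0)

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(20):
            n = rng.integers(8, 30)
            scores = np.round(rng.normal(size=n), 1)
            labels = np.zeros(n, int)
            labels[: max(1, int(n // 3))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            got = pcp.auc(scores, labels)
            assert got == pytest.approx(
                brute_force_auc(scores[labels == 1], scores[labels == 0])
            )
            assert got == pytest.approx(roc_auc_score(labels, scores))

    def test_trapezoid_dual_oracle(self, rng):
        """Mann-Whitney AUC equals the trapezoidal area under the ROC."""
        for _ in range(20):
            scores = np.round(rng.normal(size=150), 1)
            labels = (rng.uniform(size=150) < 0.3).astype(int)
            if labels.sum() in (0, 150):
                continue
            roc = pcp.roc_curve(scores, labels)
            area = np.trapezoid(roc.sensitivity, 1 - roc.specificity)
            assert abs(pcp.auc(scores, labels) - area) < 1e-12

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=250)
        labels = (rng.uniform(size=250) < 0.3).astype(int)
        base = pcp.auc(scores, labels)
        for transform in (np.exp, lambda s: 3 * s - 7, lambda s: s**3):
            assert pcp.auc(transform(scores), labels) == pytest.approx(base)


class TestBootstrapAuc:
    def test_perfect_marker_degenerate_ci(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        est = pcp.bootstrap_auc(scores, labels, B=200, seed=1)
        assert np.all(est.replicates == 1.0)
        assert (est.ci_low, est.ci_high) == (1.0, 1.0)

    def test_seed_determinism(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.uniform(size=100) < 0.4).astype(int)
        a = pcp.bootstrap_auc(scores, labels, B=150, seed=7)
        b = pcp.bootstrap_auc(scores, labels, B=150, seed=7)
        assert np.array_equal(a.replicates, b.replicates)
        assert a.ci_low == b.ci_low

    def test_ci_ordered_inside_unit_interval(self, rng):
        scores = rng.normal(size=80)
        labels = (rng.uniform(size=80) < 0.5).astype(int)
        est = pcp.bootstrap_auc(scores, labels, B=200, seed=3)
        assert 0 <= est.ci_low <= est.ci_high <= 1


class TestCompareAucs:
    def test_identity_and_monotone_invariance(self, rng):
        scores = rng.normal(size=120)
        labels = (rng.uniform(size=120) < 0.4).astype(int)
        same = pcp.compare_aucs(scores, scores, labels, B=100, seed=2)
        assert np.all(same.replicates == 0)
        doubled = pcp.compare_aucs(scores, 2 * scores, labels, B=100, seed=2)
        assert np.all(doubled.replicates == 0)
        assert not doubled.significant

    def test_extreme_case_significant(self, rng):
        labels = np.r_[np.ones(200, int), np.zeros(200, int)]
        perfect = labels + rng.uniform(0, 0.5, size=400)
        noise = rng.normal(size=400)
        cmp = pcp.compare_aucs(perfect, noise, labels, B=200, seed=5)
        assert cmp.significant and cmp.ci_low > 0


class TestUnivariateLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # marker+: 20 cases, 10 controls; marker-: 10 cases, 20 controls
        marker = np.r_[np.ones(30), np.zeros(30)]
        labels = np.r_[np.ones(20, int), np.zeros(10, int), np.ones(10, int), np.zeros(20, int)]
        fit = pcp.univariate_logistic(marker, labels)
        assert fit.odds_ratio == pytest.approx(4.0, rel=1e-6)  # ad/bc
        assert fit.or_ci_low < 4.0 < fit.or_ci_high
        assert not fit.separation

    def test_null_marker_or_near_one(self, rng):
        marker = rng.normal(size=2000)
        labels = (rng.uniform(size=2000) < 0.3).astype(int)
        fit = pcp.univariate_logistic(marker, labels)
        assert 0.8 < fit.odds_ratio < 1.25
        assert fit.p_value > 0.01

    def test_separation_flagged(self):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        fit = pcp.univariate_logistic(labels.astype(float), labels)
        assert fit.separation
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError):
            pcp.univariate_logistic(np.ones(20), np.r_[np.ones(10, int), np.zeros(10, int)])

    def test_p_display_convention(self, rng):
        x = np.r_[rng.normal(2, 1, 300), rng.normal(0, 1, 300)]
        y = np.r_[np.ones(300, int), np.zeros(300, int)]
        fit = pcp.univariate_logistic(x, y)
        assert fit.p_display() == "<0.001"


class TestHosmerLemeshow:
    def test_exact_calibration_gives_zero(self):
        # 5 blocks of 10 with constant risk and exactly matching events
        probs, labels = [], []
        for p, k in [(0.1, 1), (0.3, 3), (0.5, 5), (0.7, 7), (0.9, 9)]:
            probs += [p] * 10
            labels += [1] * k + [0] * (10 - k)
        res = pcp.hosmer_lemeshow(np.array(probs), np.array(labels), g=5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.observed.sum() == sum(labels)

    def test_direct_evaluation_of_statistic(self):
        # groups: p=.2 O=3; p=.5 O=7; p=.8 O=8  (n=10 each)
        probs = np.r_[[0.2] * 10, [0.5] * 10, [0.8] * 10]
        labels = np.r_[
            [1] * 3 + [0] * 7, [1] * 7 + [0] * 3, [1] * 8 + [0] * 2
        ].astype(int)
        res = pcp.hosmer_lemeshow(probs, labels, g=3)
        expected = (3 - 2) ** 2 / (10 * 0.2 * 0.8) + (7 - 5) ** 2 / (10 * 0.25) + 0.0
        assert res.statistic == pytest.approx(expected)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1))

    def test_well_specified_null_p_uniform(self):
        """Under a correctly specified logistic model the HL p-values are
        approximately uniform."""
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=400)
            p_true = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
            y = (rng.uniform(size=400) < p_true).astype(int)
            fit = pcp.univariate_logistic(x, y)
            pvals.append(pcp.hosmer_lemeshow(fit.fitted, y).p_value)
        pvals = np.array(pvals)
        assert 0.4 < pvals.mean() < 0.6
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pcp.hosmer_lemeshow([0.5] * 5, [0, 1, 0, 1, 0], g=10)  # n < g
        with pytest.raises(ValueError):
            pcp.hosmer_lemeshow([0.0, 0.5, 0.7], [0, 1, 0], g=3)  # p == 0


class TestBootstrapHl:
    def test_single_resample(self, rng):
        x = rng.normal(size=100)
        y = (rng.uniform(size=100) < 0.4).astype(int)
        pv = pcp.bootstrap_hl(x, y, B=1, seed=0)
        assert pv.shape == (1,)
        assert 0 <= pv[0] <= 1

    def test_seed_determinism(self, rng):
        x = rng.normal(size=150)
        y = (rng.uniform(size=150) < 0.4).astype(int)
        assert np.array_equal(
            pcp.bootstrap_hl(x, y, B=50, seed=4), pcp.bootstrap_hl(x, y, B=50, seed=4)
        )

    def test_well_specified_marker_distribution_shifted_down(self):
        """Resample-refit HL p-values are anti-conservative even for a
        well-specified marker: duplicated subjects in a bootstrap resample
        overdisperse the group counts relative to the binomial variance in
        the HL denominator, inflating the statistic.  The distribution is
        shifted below uniform but not degenerate at zero."""
        rng = np.random.default_rng(77)
        x = rng.normal(size=500)
        p_true = 1 / (1 + np.exp(-(-0.3 + 0.9 * x)))
        y = (rng.uniform(size=500) < p_true).astype(int)
        pv = pcp.bootstrap_hl(x, y, B=500, seed=6)
        assert pv.mean() < 0.5  # below the uniform mean
        assert pv.std() > 0.05 and pv.max() > 0.2  # but a real distribution
        # in-sample HL on the same data stays unremarkable
        fit = pcp.univariate_logistic(x, y)
        assert pcp.hosmer_lemeshow(fit.fitted, y).p_value > 0.05
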