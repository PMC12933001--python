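"""Evaluation statistics against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy import stats as sst

from ecglvh.errors import InvalidArgumentError, UndefinedMetricError
from ecglvh.stats import (
    auroc_ci_analytic,
    auroc_empirical,
    binary_metrics,
    bland_altman,
    classification_report,
    delong_test,
    regression_report,
    roc_coordinates,
    youden_operating_point,
)


def brute_force_auroc(scores, labels):
    """Pair counting with half credit for ties — the definitional oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = (-np.inf, None)
    candidates = np.concatenate([np.unique(scores) - 1e-9,
                                 np.unique(scores) + 1e-9])
    for thr in candidates:
        pred = scores > thr
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, (sens, spec))
        elif abs(j - best[0]) <= 1e-12 and spec > best[1][1]:
            best = (j, (sens, spec))
    return best


class TestAuroc:
    def test_worked_example(self):
        assert auroc_empirical([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert auroc_empirical([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auroc_empirical([1.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc_empirical([0.1, 0.2], [1, 1])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 8, n) / 7.0  # heavy ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert auroc_empirical(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        labels[0], labels[1] = 0, 1
        assert auroc_empirical(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestAurocCi:
    def test_symmetric_at_half(self):
        lo, hi = auroc_ci_analytic(0.5, 40, 40)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_width_shrinks_with_n(self):
        widths = [np.diff(auroc_ci_analytic(0.8, n, n))[0]
                  for n in (10, 50, 200, 1000)]
        assert widths == sorted(widths, reverse=True)

    def test_degenerate_auc_zero_width(self):
        assert auroc_ci_analytic(1.0, 10, 10) == (1.0, 1.0)

    def test_agrees_with_bootstrap_at_moderate_n(self):
        rng = np.random.default_rng(2)
        n = 150
        pos = rng.normal(1.0, 1.0, n)
        neg = rng.normal(0.0, 1.0, n)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        auc = auroc_empirical(scores, labels)
        lo, hi = auroc_ci_analytic(auc, n, n)
        boots = []
        for _ in range(3000):
            idx_p = rng.integers(0, n, n)
            idx_n = rng.integers(0, n, n)
            boots.append(auroc_empirical(
                np.concatenate([pos[idx_p], neg[idx_n]]), labels))
        b_lo, b_hi = np.quantile(boots, [0.025, 0.975])
        assert lo == pytest.approx(b_lo, abs=0.03)
        assert hi == pytest.approx(b_hi, abs=0.03)


def permutation_delong_oracle(scores_a, scores_b, labels, n_perm, rng):
    """Paired sign-flip permutation of the AUROC difference (vectorized)."""
    labels = np.asarray(labels, bool)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    observed = abs(auroc_empirical(a, labels) - auroc_empirical(b, labels))
    n = a.size
    swap = rng.random((n_perm, n)) < 0.5
    sa = np.where(swap, b, a)
    sb = np.where(swap, a, b)

    def batched_auroc(scores):
        pos = scores[:, labels]
        neg = scores[:, ~labels]
        comp = (pos[:, :, None] > neg[:, None, :]).mean(axis=(1, 2))
        ties = (pos[:, :, None] == neg[:, None, :]).mean(axis=(1, 2))
        return comp + 0.5 * ties

    diffs = np.abs(batched_auroc(sa) - batched_auroc(sb))
    return (1 + (diffs >= observed - 1e-12).sum()) / (n_perm + 1)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        z, p, a1, a2 = delong_test(scores, scores, labels)
        assert (z, p) == (0.0, 1.0)
        assert a1 == a2

    def test_auc_estimates_match_empirical(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=100), rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        _, _, auc_a, auc_b = delong_test(a, b, labels)
        assert auc_a == pytest.approx(auroc_empirical(a, labels), abs=1e-12)
        assert auc_b == pytest.approx(auroc_empirical(b, labels), abs=1e-12)

    def test_power_against_informative_scores(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            labels = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
            informative = np.concatenate([rng.normal(1.2, 1, 100),
                                          rng.normal(0, 1, 100)])
            random_scores = rng.normal(size=200)
            _, p, _, _ = delong_test(informative, random_scores, labels)
            rejections += p < 0.05
        assert rejections >= 0.8 * n_rep

    def test_small_sample_tracks_permutation_oracle(self):
        # at n=20 the normal approximation tracks an exact paired sign-flip
        # permutation for null-like instances (exactness of the variance
        # machinery itself is checked against pROC below)
        rng = np.random.default_rng(1)
        labels = np.concatenate([np.ones(8, bool), np.zeros(12, bool)])
        a, b = rng.normal(size=20), rng.normal(size=20)
        _, p, _, _ = delong_test(a, b, labels)
        p_perm = permutation_delong_oracle(a, b, labels, 20_000,
                                           np.random.default_rng(1001))
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_matches_reference_implementation_exactly(self):
        """z and p agree with pROC's DeLong test (the canonical R
        implementation) to the solver's printed precision."""
        import subprocess
        rng = np.random.default_rng(2)
        n = 60
        labels = (rng.random(n) < 0.4).astype(int)
        labels[:2] = [0, 1]
        a = labels * 0.8 + rng.normal(0, 1, n)
        b = labels * 0.4 + rng.normal(0, 1, n)
        z, p, _, _ = delong_test(a, b, labels)
        script = (
            "suppressMessages(library(pROC));"
            f"y <- c({','.join(map(str, labels))});"
            f"a <- c({','.join(map(str, a))});"
            f"b <- c({','.join(map(str, b))});"
            "t <- roc.test(roc(y,a,quiet=TRUE), roc(y,b,quiet=TRUE),"
            "              method='delong', paired=TRUE);"
            "cat(sprintf('%.12g %.12g', t$p.value, t$statistic))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        assert p == pytest.approx(float(out[0]), rel=1e-9)
        assert z == pytest.approx(float(out[1]), rel=1e-9)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            delong_test([1, 2], [1, 2, 3], [0, 1])


class TestYouden:
    def test_separable_case(self):
        op = youden_operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert op.sensitivity == 1.0 and op.specificity == 1.0
        assert 0.2 < op.threshold < 0.8

    def test_anti_correlated_scores_degenerate(self):
        op = youden_operating_point([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        assert op.youden_j == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            op = youden_operating_point(scores, labels)
            best_j, (sens, spec) = brute_force_youden(scores, labels)
            assert op.youden_j == pytest.approx(best_j, abs=1e-9)
            assert op.specificity == pytest.approx(spec, abs=1e-9)


class TestBinaryMetrics:
    def test_perfect_and_all_negative(self):
        truth = np.array([1, 1, 0, 0], bool)
        perfect = binary_metrics(truth, truth)
        assert (perfect.sensitivity, perfect.specificity, perfect.f1) == (1, 1, 1)
        none = binary_metrics(np.zeros(4, bool), truth)
        assert (none.sensitivity, none.specificity) == (0.0, 1.0)

    def test_constructed_confusion_matrix(self):
        # 46 true positives, 54 misses, 99 true negatives, 1 false alarm:
        # the high-specificity / low-sensitivity profile of a down-biased
        # threshold classifier
        truth = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
        pred = np.concatenate([np.ones(46, bool), np.zeros(54, bool),
                               np.ones(1, bool), np.zeros(99, bool)])
        m = binary_metrics(pred, truth)
        assert m.sensitivity == pytest.approx(0.46)
        assert m.specificity == pytest.approx(0.99)
        assert m.sensitivity_ci[0] < 0.46 < m.sensitivity_ci[1]

    def test_wilson_interval_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        truth = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        pred = np.concatenate([np.ones(35, bool), np.zeros(15, bool),
                               np.zeros(50, bool)])
        m = binary_metrics(pred, truth)
        lo, hi = proportion_confint(35, 50, method="wilson")
        assert m.sensitivity_ci == pytest.approx((lo, hi))


class TestRegressionReport:
    def test_identity_prediction(self):
        obs = np.linspace(30, 90, 50)
        r = regression_report(obs, obs)
        assert (r.mae, r.me) == (0.0, 0.0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.ols_slope == pytest.approx(1.0)
        assert r.ols_intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift(self):
        rng = np.random.default_rng(8)
        obs = rng.normal(50, 10, 80)
        r = regression_report(obs - 5.0, obs)
        assert r.me == pytest.approx(-5.0)
        assert r.mae == pytest.approx(5.0)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(9)
        pred, obs = rng.normal(size=40), rng.normal(size=40)
        a = regression_report(pred, obs, seed=11)
        b = regression_report(pred, obs, seed=11)
        assert a.mae_ci == b.mae_ci and a.me_ci == b.me_ci

    def test_bootstrap_ci_covers_folded_normal_mean(self):
        # errors ~ N(0, 2): E|err| = 2 sqrt(2/pi) ~ 1.596
        target = 2.0 * np.sqrt(2.0 / np.pi)
        rng = np.random.default_rng(10)
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            obs = rng.normal(50, 10, 50)
            pred = obs + rng.normal(0, 2.0, 50)
            r = regression_report(pred, obs, n_boot=2000, seed=rep)
            covered += r.mae_ci[0] <= target <= r.mae_ci[1]
        assert covered >= 0.93 * n_rep

    def test_too_few_points(self):
        with pytest.raises(InvalidArgumentError):
            regression_report([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_zero_differences(self):
        x = np.linspace(0, 1, 20)
        ba = bland_altman(x, x)
        assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_limits_factor_on_standard_normal(self):
        rng = np.random.default_rng(11)
        d = rng.normal(size=100_000)
        ba = bland_altman(d, np.zeros_like(d))
        assert ba.loa_low == pytest.approx(-1.96, abs=0.02)
        assert ba.loa_high == pytest.approx(1.96, abs=0.02)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(12)
        pred, obs = rng.normal(size=60), rng.normal(size=60)
        base = bland_altman(pred, obs)
        shifted = bland_altman(pred + 3.5, obs)
        assert shifted.bias == pytest.approx(base.bias + 3.5, abs=1e-12)
        assert shifted.loa_low == pytest.approx(base.loa_low + 3.5, abs=1e-9)
        assert shifted.loa_high == pytest.approx(base.loa_high + 3.5, abs=1e-9)

    def test_loa_ci_half_width_formula(self):
        rng = np.random.default_rng(13)
        pred, obs = rng.normal(size=30), rng.normal(size=30)
        ba = bland_altman(pred, obs)
        half = sst.t.ppf(0.975, 29) * np.sqrt(3 * ba.sd**2 / 30)
        assert ba.loa_low_ci[1] - ba.loa_low_ci[0] == pytest.approx(2 * half)


class TestReports:
    def test_classification_report_consistency(self):
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 2, 200).astype(bool)
        labels[:2] = [True, False]
        scores = labels + rng.normal(0, 0.8, 200)
        report = classification_report(scores, labels, model_variant="toy")
        assert report.auroc_ci[0] <= report.auroc <= report.auroc_ci[1]
        assert report.n_positive == labels.sum()
        pred = scores > report.operating_point.threshold
        assert report.classification.sensitivity == pytest.approx(
            (pred & labels).sum() / labels.sum())

    def test_roc_coordinates_monotone(self):
        rng = np.random.default_rng(15)
        labels = rng.integers(0, 2, 100).astype(bool)
        labels[:2] = [True, False]
        coords = roc_coordinates(rng.normal(size=100), labels)
        assert np.all(np.diff(coords[:, 1]) >= 0)  # FPR grows as threshold falls
        assert np.all(np.diff(coords[:, 2]) >= 0)
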