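"""Diagnostic and regression statistics for model evaluation.

Implements the evaluation battery: empirical AUROC (Mann-Whitney form) with
the Hanley-McNeil analytic confidence interval, the fast (midrank) DeLong test
for paired AUROC differences, Youden-J optimized operating points, confusion
matrix metrics with Wilson score intervals, regression accuracy (MAE/ME with
seeded bootstrap intervals, Pearson, OLS) and Bland-Altman agreement with
confidence intervals on the limits of agreement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sst
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidArgumentError, UndefinedMetricError

logger = logging.getLogger(__name__)


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise InvalidArgumentError("scores and labels must be the same length")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("both classes must be present")
    return pos, neg


def auroc_empirical(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Computed through midranks, which is algebraically identical to
    brute-force pair counting with half-credit for ties.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    ranks = sst.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def auroc_ci_analytic(auc: float, n_pos: int, n_neg: int,
                      level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil analytic confidence interval, clipped to [0, 1]."""
    if n_pos < 1 or n_neg < 1:
        raise InvalidArgumentError("need at least one sample per class")
    if auc in (0.0, 1.0):
        logger.warning("degenerate AUROC %.1f: analytic SE is 0", auc)
        return float(auc), float(auc)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2))
        / (n_pos * n_neg)
    )
    z = sst.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1))


# ---------------------------------------------------------------------------
# DeLong

def _midrank_structure(scores, labels):
    """Placement values V10 (positives) and V01 (negatives) plus the AUC."""
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    tz = sst.rankdata(np.concatenate([pos, neg]))
    tx = sst.rankdata(pos)
    ty = sst.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Fast DeLong comparison of two correlated AUROCs.

    Returns (z, two-sided p, auc_a, auc_b). Identical score vectors give
    z = 0, p = 1 exactly.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise InvalidArgumentError("paired score vectors must be the same length")
    v10a, v01a, auc_a = _midrank_structure(scores_a, labels)
    v10b, v01b, auc_b = _midrank_structure(scores_b, labels)
    m, n = v10a.size, v01a.size

    def _cov(u, v):
        return np.cov(np.vstack([u, v]), ddof=1) if u.size > 1 else np.zeros((2, 2))

    s10 = _cov(v10a, v10b)
    s01 = _cov(v01a, v01b)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = float(diff / np.sqrt(var))
        p = float(2.0 * sst.norm.sf(abs(z)))
    return z, p, auc_a, auc_b


# ---------------------------------------------------------------------------
# operating points and confusion metrics

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_operating_point(scores, labels) -> OperatingPoint:
    """Threshold maximizing TPR - FPR; ties broken by higher specificity.

    Candidate thresholds are the midpoints between consecutive distinct
    scores plus one below the minimum and one above the maximum (rule:
    positive iff score > threshold).
    """
    pos, neg = _split_scores(scores, labels)
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    candidates = np.concatenate([
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 1.0],
    ])
    sens = (pos[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] <= candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    best = tied[np.argmax(spec[tied])]
    if best_j <= 1e-12:
        logger.warning(
            "Youden J is not positive (%.3f): scores carry no (or inverted) signal",
            best_j,
        )
    return OperatingPoint(float(candidates[best]), float(sens[best]), float(spec[best]))


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int


def binary_metrics(labels_pred, labels_true, level: float = 0.95) -> BinaryMetrics:
    """Confusion-matrix metrics; sensitivity/specificity CIs by Wilson score."""
    pred = np.asarray(labels_pred).astype(bool)
    true = np.asarray(labels_true).astype(bool)
    if pred.shape != true.shape or pred.size == 0:
        raise InvalidArgumentError("label vectors must be non-empty and paired")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    tn = int((~pred & ~true).sum())
    fn = int((~pred & true).sum())
    if tp + fn == 0:
        raise UndefinedMetricError("no positives in truth: sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetricError("no negatives in truth: specificity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=1 - level, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=1 - level, method="wilson")
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    return BinaryMetrics(
        sensitivity=float(sens), sensitivity_ci=tuple(map(float, sens_ci)),
        specificity=float(spec), specificity_ci=tuple(map(float, spec_ci)),
        f1=float(f1), tp=tp, fp=fp, tn=tn, fn=fn,
    )


# ---------------------------------------------------------------------------
# regression accuracy and agreement

@dataclass(frozen=True)
class RegressionReport:
    mae: float
    mae_ci: tuple
    me: float
    me_ci: tuple
    residual_skew: float
    pearson_r: float
    pearson_p: float
    ols_slope: float
    ols_intercept: float
    adjusted_r2: float
    n: int
    bootstrap_seed: int


def regression_report(predicted, observed, n_boot: int = 5000,
                      seed: int = 0, level: float = 0.95) -> RegressionReport:
    """MAE/ME with percentile-bootstrap CIs, Pearson r, OLS fit, residual skew.

    Mean error uses the (prediction - observation) convention, so systematic
    underestimation is negative.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise InvalidArgumentError("need at least 3 paired values")
    diff = predicted - observed
    mae, me = float(np.abs(diff).mean()), float(diff.mean())

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diff.size, size=(n_boot, diff.size))
    boot = diff[idx]
    alpha = (1 - level) / 2
    mae_ci = tuple(np.quantile(np.abs(boot).mean(axis=1), [alpha, 1 - alpha]))
    me_ci = tuple(np.quantile(boot.mean(axis=1), [alpha, 1 - alpha]))

    r, p = sst.pearsonr(predicted, observed)
    ols = sst.linregress(observed, predicted)
    r2 = ols.rvalue**2
    n = diff.size
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionReport(
        mae=mae, mae_ci=tuple(map(float, mae_ci)),
        me=me, me_ci=tuple(map(float, me_ci)),
        residual_skew=float(sst.skew(diff)),
        pearson_r=float(r), pearson_p=float(p),
        ols_slope=float(ols.slope), ols_intercept=float(ols.intercept),
        adjusted_r2=float(adj_r2), n=n, bootstrap_seed=seed,
    )


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    loa_low_ci: tuple
    loa_high_ci: tuple
    sd: float
    n: int


def bland_altman(predicted, observed, level: float = 0.95) -> BlandAltman:
    """Limits of agreement bias +- 1.96 sd with t-based CIs on each limit.

    The half-width of each limit's CI is t_{0.975, n-1} * sqrt(3 sd^2 / n).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise InvalidArgumentError("need at least 3 paired values")
    d = predicted - observed
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        logger.warning("zero-variance differences: limits of agreement collapse")
    z = sst.norm.ppf(0.5 + level / 2.0)
    loa_low, loa_high = bias - z * sd, bias + z * sd
    n = d.size
    half = float(sst.t.ppf(0.975, n - 1) * np.sqrt(3.0 * sd**2 / n))
    return BlandAltman(
        bias=bias, loa_low=float(loa_low), loa_high=float(loa_high),
        loa_low_ci=(loa_low - half, loa_low + half),
        loa_high_ci=(loa_high - half, loa_high + half),
        sd=sd, n=n,
    )


# ---------------------------------------------------------------------------
# aggregate report

@dataclass
class EvaluationReport:
    """All diagnostic and regression metrics for one model on one split."""

    model_variant: str = ""
    n: int = 0
    n_positive: int = 0
    auroc: float | None = None
    auroc_ci: tuple | None = None
    operating_point: OperatingPoint | None = None
    classification: BinaryMetrics | None = None
    regression: RegressionReport | None = None
    agreement: BlandAltman | None = None
    delong_vs: str | None = None
    delong_p: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=float)


def classification_report(scores, labels, model_variant: str = "") -> EvaluationReport:
    """AUROC + analytic CI + Youden operating point + confusion metrics."""
    labels_arr = np.asarray(labels).astype(bool)
    auc = auroc_empirical(scores, labels_arr)
    ci = auroc_ci_analytic(auc, int(labels_arr.sum()), int((~labels_arr).sum()))
    op = youden_operating_point(scores, labels_arr)
    pred = np.asarray(scores, dtype=float) > op.threshold
    metrics = binary_metrics(pred, labels_arr)
    return EvaluationReport(
        model_variant=model_variant,
        n=int(labels_arr.size),
        n_positive=int(labels_arr.sum()),
        auroc=auc,
        auroc_ci=ci,
        operating_point=op,
        classification=metrics,
    )


def roc_coordinates(scores, labels) -> np.ndarray:
    """(threshold, FPR, TPR) rows for plotting, over all distinct thresholds."""
    pos, neg = _split_scores(scores, labels)
    thresholds = np.unique(np.asarray(scores, dtype=float))[::-1]
    tpr = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] > thresholds[:, None]).mean(axis=1)
    return np.column_stack([thresholds, fpr, tpr])
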