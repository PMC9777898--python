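"""Evaluation harness: ROC/AUC with DeLong variance, paired AUC comparison,
stratified cross-validation, threshold metrics and normalized confusion
matrices.

AUC follows the Mann-Whitney convention (ties get half credit), and all
variance machinery is the structural-components (placement-value) estimator
of DeLong et al., so the single-model confidence interval and the paired
two-model test share one statistical footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "RocCurve",
    "DelongResult",
    "CVResult",
    "ThresholdMetrics",
    "ChapterModelReport",
    "roc_auc",
    "auc_ci",
    "delong_test",
    "cross_validate",
    "threshold_metrics",
    "evaluate_chapter",
]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int).reshape(-1)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


@dataclass
class RocCurve:
    """ROC operating points (thresholds descending) plus the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _placements(y: np.ndarray, scores: np.ndarray):
    """DeLong placement values V10 (positives) and V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def mann_whitney_auc(labels, scores) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic."""
    y = _check_binary(labels)
    v10, _ = _placements(y, np.asarray(scores, dtype=float).reshape(-1))
    return float(v10.mean())


def roc_auc(labels, scores) -> RocCurve:
    """ROC curve plus Mann-Whitney AUC."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).reshape(-1)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    fpr, tpr, thr = roc_curve(y, s)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=mann_whitney_auc(y, s))


def _auc_variance(y: np.ndarray, scores: np.ndarray):
    v10, v01 = _placements(y, scores)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(v10.mean()), s10 / m + s01 / n, m, n


def auc_ci(labels, scores, alpha: float = 0.05):
    """Normal-approximation AUC confidence interval from DeLong variance.

    Returns ``(lo, hi, degenerate)``; a zero-variance estimate (e.g. a
    perfect AUC at tiny n) is widened by the 1/(m*n) continuity floor and
    flagged ``degenerate=True``.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).reshape(-1)
    auc, var, m, n = _auc_variance(y, s)
    degenerate = var <= 0.0
    if degenerate:
        var = 1.0 / (m * n)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)), degenerate


@dataclass
class DelongResult:
    """Paired AUC comparison of two models on the same subjects."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_two_sided: float
    degenerate: bool = False


def delong_test(labels, scores_a, scores_b) -> DelongResult:
    """DeLong two-sided paired test of AUC_a = AUC_b.

    Uses midrank placement values per model; the variance of the AUC
    difference accounts for the pairing via the placement covariances.
    """
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float).reshape(-1)
    sb = np.asarray(scores_b, dtype=float).reshape(-1)
    if sa.shape != sb.shape or sa.size != y.size:
        raise ValueError("both score vectors must cover the same subjects")
    va10, va01 = _placements(y, sa)
    vb10, vb01 = _placements(y, sb)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    s10 = np.cov(np.stack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0.0:
        # zero estimated variance: identical placements (p = 1) or a
        # nonzero difference with no sampling variability (flagged)
        if abs(diff) > 1e-12:
            return DelongResult(
                auc_a, auc_b, 0.0, float(np.sign(diff)) * np.inf, 0.0, degenerate=True
            )
        return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
    z = diff / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(var), float(z), float(min(p, 1.0)))


@dataclass
class CVResult:
    """Per-fold held-out AUCs with their mean and spread."""

    fold_aucs: list[float]
    mean: float
    sd: float
    ci: tuple[float, float]
    skipped_folds: list[int] = field(default_factory=list)


def _take(features, idx):
    if features is None:
        return None
    if isinstance(features, (tuple, list)):
        return type(features)(_take(f, idx) for f in features)
    return np.asarray(features)[idx]


def cross_validate(features, labels, split_plan, trainer) -> CVResult:
    """K-fold CV over the plan's train ids.

    ``features`` is an array or tuple of arrays whose rows align with
    ``split_plan.train_ids``; ``trainer(train_features, train_labels)``
    must return a ``predict(features) -> scores`` callable.  Folds whose
    validation part is single-class are skipped with a warning.
    """
    y = np.asarray(labels, dtype=int).reshape(-1)
    ids = split_plan.train_ids
    if y.size != len(ids):
        raise ValueError("labels must align with split_plan.train_ids")
    index_of = {sid: i for i, sid in enumerate(ids)}
    fold_aucs: list[float] = []
    skipped: list[int] = []
    for fold in range(split_plan.n_folds):
        val_idx = np.array([index_of[sid] for sid in split_plan.fold_ids(fold)])
        tr_idx = np.array([i for i in range(len(ids)) if i not in set(val_idx)])
        y_val = y[val_idx]
        if y_val.min() == y_val.max():
            warnings.warn(f"fold {fold} has a single class; skipped")
            skipped.append(fold)
            continue
        predict_fn = trainer(_take(features, tr_idx), y[tr_idx])
        scores = np.asarray(predict_fn(_take(features, val_idx))).reshape(-1)
        fold_aucs.append(mann_whitney_auc(y_val, scores))
    if not fold_aucs:
        raise ValueError("every fold was skipped; cannot cross-validate")
    arr = np.asarray(fold_aucs)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    half = norm.ppf(0.975) * sd / np.sqrt(arr.size) if arr.size > 1 else 0.0
    ci = (float(np.clip(mean - half, 0, 1)), float(np.clip(mean + half, 0, 1)))
    return CVResult(fold_aucs=fold_aucs, mean=mean, sd=sd, ci=ci, skipped_folds=skipped)


@dataclass
class ThresholdMetrics:
    """Standard 2x2 metrics at a fixed probability threshold."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float | None  # None when no subject is predicted positive
    f1: float | None
    confusion: np.ndarray  # normalized, rows = true class, rows sum to 1
    counts: dict

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "counts": self.counts,
        }


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (recall)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def threshold_metrics(labels, scores, threshold: float = 0.5) -> ThresholdMetrics:
    """Accuracy/sensitivity/specificity/precision/F1 and confusion matrix."""
    y = _check_binary(labels)
    pred = (np.asarray(scores, dtype=float).reshape(-1) >= threshold).astype(int)
    tp = int(((y == 1) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / y.size
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    f1 = f1_score(precision, sens) if precision is not None else None
    confusion = np.array([[tn, fp], [fn, tp]], dtype=float)
    confusion /= confusion.sum(axis=1, keepdims=True)
    return ThresholdMetrics(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=precision,
        f1=f1,
        confusion=confusion,
        counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


@dataclass
class ChapterModelReport:
    """Per-chapter evaluation bundle: CV AUC, test metrics with refit spread."""

    chapter: str
    n_refits: int
    metric_mean: dict
    metric_sd: dict
    test_auc_mean: float
    test_auc_sd: float
    auc_ci: tuple[float, float]
    cv: CVResult | None
    confusion_mean: np.ndarray
    refit_metrics: list[ThresholdMetrics]
    roc: RocCurve

    def as_dict(self) -> dict:
        return {
            "chapter": self.chapter,
            "n_refits": self.n_refits,
            "metric_mean": self.metric_mean,
            "metric_sd": self.metric_sd,
            "test_auc_mean": self.test_auc_mean,
            "test_auc_sd": self.test_auc_sd,
            "auc_ci": list(self.auc_ci),
            "cv_auc_mean": None if self.cv is None else self.cv.mean,
            "cv_auc_sd": None if self.cv is None else self.cv.sd,
            "cv_auc_ci": None if self.cv is None else list(self.cv.ci),
            "cv_fold_aucs": None if self.cv is None else self.cv.fold_aucs,
            "confusion_mean": self.confusion_mean.tolist(),
            "refits": [m.as_dict() for m in self.refit_metrics],
        }


def evaluate_chapter(
    chapter: str,
    fit_predict,
    test_labels,
    n_refits: int = 3,
    seeds=None,
    train_ids=None,
    test_ids=None,
    cv: CVResult | None = None,
    threshold: float = 0.5,
) -> ChapterModelReport:
    """Refit/evaluate on the held-out test set ``n_refits`` times.

    ``fit_predict(seed)`` must train from scratch with that seed and return
    test-set scores.  If both id lists are supplied, any overlap (training
    leakage into the test set) raises a hard error.
    """
    if train_ids is not None and test_ids is not None:
        leak = set(train_ids) & set(test_ids)
        if leak:
            raise ValueError(f"test subjects appear in training data: {sorted(leak)}")
    y = _check_binary(test_labels)
    seeds = list(seeds) if seeds is not None else list(range(n_refits))
    if len(seeds) != n_refits:
        raise ValueError("need one seed per refit")
    metrics_list: list[ThresholdMetrics] = []
    aucs: list[float] = []
    first_scores = None
    for sd in seeds:
        scores = np.asarray(fit_predict(sd)).reshape(-1)
        if first_scores is None:
            first_scores = scores
        metrics_list.append(threshold_metrics(y, scores, threshold))
        aucs.append(mann_whitney_auc(y, scores))
    names = ("accuracy", "sensitivity", "specificity", "precision", "f1")
    metric_mean = {}
    metric_sd = {}
    for nm in names:
        vals = [getattr(m, nm) for m in metrics_list]
        if any(v is None for v in vals):
            metric_mean[nm] = None
            metric_sd[nm] = None
        else:
            metric_mean[nm] = float(np.mean(vals))
            metric_sd[nm] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    lo, hi, _ = auc_ci(y, first_scores)
    return ChapterModelReport(
        chapter=chapter,
        n_refits=n_refits,
        metric_mean=metric_mean,
        metric_sd=metric_sd,
        test_auc_mean=float(np.mean(aucs)),
        test_auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        auc_ci=(lo, hi),
        cv=cv,
        confusion_mean=np.mean([m.confusion for m in metrics_list], axis=0),
        refit_metrics=metrics_list,
        roc=roc_auc(y, first_scores),
    )
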