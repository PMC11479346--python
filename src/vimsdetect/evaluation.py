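"""Classification metrics and normalized-time trend analysis.

Metrics follow the usual definitions: accuracy and Cohen's kappa at a fixed
probability threshold, ROC-AUC by the trapezoidal rule, PR-AUC as average
precision (the step-wise, non-interpolated rule; trapezoids over PR points
overestimate).  Trend analysis maps every session onto a common normalized
time axis of 1000 segments and correlates each feature's mean trajectory
with the mean VIMS-level trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, cohen_kappa_score,
                             precision_recall_curve, roc_auc_score, roc_curve)

from .features import FEATURE_COLUMNS
from .model import FoldResult
from .preprocess import LabelSeries, StandardizedFeatures
from .recordings import ValidationError

__all__ = [
    "EvalResult",
    "TrendResult",
    "binary_metrics",
    "recall_precision_at",
    "evaluate_folds",
    "normalize_time_resample",
    "trend_analysis",
]


def binary_metrics(y_true, y_prob, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, Cohen's kappa, ROC-AUC and PR-AUC for one test set.

    AUCs require both classes in ``y_true``; otherwise they are NaN and a
    warning is issued.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValidationError("y_true and y_prob must have the same length")
    y_pred = (y_prob >= threshold).astype(int)
    acc = float(np.mean(y_pred == y_true))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant marginals make kappa 0/0
        kappa = float(cohen_kappa_score(y_true, y_pred))
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUCs undefined", stacklevel=2)
        roc = pr = float("nan")
    else:
        roc = float(roc_auc_score(y_true, y_prob))
        pr = float(average_precision_score(y_true, y_prob))
    return {"accuracy": acc, "kappa": kappa, "roc_auc": roc, "pr_auc": pr}


def recall_precision_at(y_true, y_prob, threshold: float = 0.5) -> tuple[float, float]:
    """(recall, precision) at a fixed threshold; precision is NaN when no
    positives are predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = (np.asarray(y_prob, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return float(recall), float(precision)


@dataclass
class EvalResult:
    """Per-participant metric rows, their arithmetic mean, and the ROC /
    precision-recall curve point sets behind the AUCs."""

    per_participant: pd.DataFrame  # index participant_id
    mean_row: pd.Series
    roc_curves: dict = None        # participant -> (fpr, tpr, thresholds)
    pr_curves: dict = None         # participant -> (precision, recall, thresholds)

    def summary(self) -> pd.DataFrame:
        out = self.per_participant.copy()
        out.loc["Mean"] = self.mean_row
        return out


def evaluate_folds(folds: list[FoldResult], threshold: float = 0.5) -> EvalResult:
    rows, rocs, prs = {}, {}, {}
    for fold in folds:
        rows[fold.participant_id] = binary_metrics(fold.y_true, fold.y_prob, threshold)
        if len(np.unique(fold.y_true)) > 1:
            rocs[fold.participant_id] = roc_curve(fold.y_true, fold.y_prob)
            prs[fold.participant_id] = precision_recall_curve(fold.y_true, fold.y_prob)
    table = pd.DataFrame(rows).T
    table.index.name = "participant_id"
    return EvalResult(per_participant=table, mean_row=table.mean(axis=0),
                      roc_curves=rocs, pr_curves=prs)


# -- trend analysis ---------------------------------------------------------


def normalize_time_resample(series: np.ndarray, n_segments: int = 1000) -> np.ndarray:
    """Linear interpolation of a series onto ``n_segments`` equally spaced
    points of normalized time [0, 1]."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValidationError("series must have at least 2 points to resample")
    src = np.linspace(0.0, 1.0, series.size)
    dst = np.linspace(0.0, 1.0, n_segments)
    return np.interp(dst, src, series)


@dataclass
class TrendResult:
    """Normalized-time cohort trends and feature-VIMS correlations."""

    grid: np.ndarray                 # n_segments points in [0, 1]
    feature_mean: pd.DataFrame       # n_segments x 23
    feature_ci_low: pd.DataFrame
    feature_ci_high: pd.DataFrame
    vims_mean: np.ndarray
    vims_ci_low: np.ndarray
    vims_ci_high: np.ndarray
    accuracy_mean: np.ndarray | None
    correlations: pd.DataFrame       # per feature: R, R2


def _mean_ci(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, low, high) across axis 0 with a normal-approximation 95% CI."""
    mean = np.nanmean(stack, axis=0)
    n = stack.shape[0]
    if n >= 2:
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return mean, mean - 1.96 * sem, mean + 1.96 * sem


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def trend_analysis(sessions: list[tuple[StandardizedFeatures, LabelSeries, np.ndarray | None]],
                   n_segments: int = 1000) -> TrendResult:
    """Cohort trends on the normalized time axis.

    Each session's feature series, VIMS-level series and (optionally) its
    0/1 prediction-correctness series are resampled to ``n_segments``
    points; the cohort mean and 95% CI (mean +/- 1.96 SEM) are taken per
    segment, and each feature's Pearson R (and R^2) against the mean
    VIMS-level trend is reported.
    """
    if len(sessions) < 2:
        raise ValidationError("trend analysis needs at least 2 sessions")
    feat_stacks = {col: [] for col in FEATURE_COLUMNS}
    vims_stack, correct_stack = [], []
    for feats, labels, correctness in sessions:
        tbl = feats.table.loc[feats.table.index.isin(labels.timestamps)]
        for col in FEATURE_COLUMNS:
            feat_stacks[col].append(
                normalize_time_resample(tbl[col].to_numpy(dtype=float), n_segments))
        vims_stack.append(
            normalize_time_resample(labels.vims_level.astype(float), n_segments))
        if correctness is not None:
            correct_stack.append(
                normalize_time_resample(np.asarray(correctness, dtype=float), n_segments))

    grid = np.linspace(0.0, 1.0, n_segments)
    vims_mean, vims_lo, vims_hi = _mean_ci(np.vstack(vims_stack))
    means, lows, highs, corr = {}, {}, {}, {}
    for col in FEATURE_COLUMNS:
        m, lo, hi = _mean_ci(np.vstack(feat_stacks[col]))
        means[col], lows[col], highs[col] = m, lo, hi
        r = _pearson(m, vims_mean)
        corr[col] = {"R": r, "R2": r * r if np.isfinite(r) else float("nan")}
    accuracy_mean = (np.nanmean(np.vstack(correct_stack), axis=0)
                     if correct_stack else None)
    return TrendResult(
        grid=grid,
        feature_mean=pd.DataFrame(means, index=grid),
        feature_ci_low=pd.DataFrame(lows, index=grid),
        feature_ci_high=pd.DataFrame(highs, index=grid),
        vims_mean=vims_mean, vims_ci_low=vims_lo, vims_ci_high=vims_hi,
        accuracy_mean=accuracy_mean,
        correlations=pd.DataFrame(corr).T,
    )
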