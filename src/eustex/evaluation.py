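"""Validation protocols and diagnostic metrics.

Two protocols mirror standard practice for small clinical cohorts:

* repeated stratified half-and-half validation — each trial randomly assigns
  half of every class to training and half to testing (200 trials by
  default), and metrics are averaged over trials with their standard error;
* leave-one-out cross-validation — every case is tested once against a model
  trained on all others, giving a single pooled confusion matrix.

Pancreatic cancer is the positive class. Metrics with a zero denominator in
a trial are flagged undefined and excluded from that metric's average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (SvmConfig, apply_scaler, fit_scaler, predict,
                         train_svm)

METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint stratified train/test case-index lists."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-trial diagnostic metrics (percent) and their aggregate.

    ``mean``/``se`` hold, per metric, the average over the trials where the
    metric was defined and its standard error (sample sd / sqrt(n_trials));
    ``n_undefined`` counts excluded trials per metric.
    """

    per_trial: pd.DataFrame
    mean: dict[str, float]
    se: dict[str, float]
    n_trials: int
    n_undefined: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "se": self.se})


def stratified_half_split(labels: Sequence[int], seed: int) -> SplitPlan:
    """Uniform random half/half split, stratified per class.

    For each class, ``floor(n_class / 2)`` cases go to training and the rest
    to testing. Reproducible: fully determined by ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in sorted(np.unique(labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 cases")
        perm = rng.permutation(idx)
        n_train = idx.size // 2
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return SplitPlan(train_idx=np.sort(np.concatenate(train_parts)),
                     test_idx=np.sort(np.concatenate(test_parts)),
                     seed=seed)


def confusion_from_predictions(y_true: np.ndarray,
                               y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV in percent.

    A zero denominator yields NaN (undefined) for that metric.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
    }


def _one_trial(table: pd.DataFrame, features: Sequence[str] | None,
               select_k: int | None, seed: int,
               svm_config: SvmConfig) -> dict[str, float]:
    split = stratified_half_split(table["label"].to_numpy(), seed)
    train = table.iloc[split.train_idx]
    test = table.iloc[split.test_idx]
    if features is None:
        if select_k is None:
            raise ValueError("give either a feature list or select_k")
        # nested mode: rank features on the training half only
        from .feature_selection import rank_features
        features = list(rank_features(train, m=select_k).selected)
    scaler = fit_scaler(train, features)
    model = train_svm(apply_scaler(scaler, train), features, svm_config)
    y_pred = predict(model, apply_scaler(scaler, test))
    return confusion_metrics(
        confusion_from_predictions(test["label"].to_numpy(), y_pred))


def _aggregate(rows: list[dict[str, float]]) -> MetricsReport:
    per_trial = pd.DataFrame(rows)
    mean, se, n_undef = {}, {}, {}
    n = len(per_trial)
    for m in METRICS:
        vals = per_trial[m].to_numpy()
        ok = np.isfinite(vals)
        n_undef[m] = int((~ok).sum())
        defined = vals[ok]
        mean[m] = float(defined.mean()) if defined.size else float("nan")
        se[m] = (float(defined.std(ddof=1) / np.sqrt(n))
                 if defined.size > 1 else 0.0)
    return MetricsReport(per_trial=per_trial, mean=mean, se=se,
                         n_trials=n, n_undefined=n_undef)


def half_and_half_eval(table: pd.DataFrame,
                       features: Sequence[str] | None,
                       n_trials: int = 200, seed: int = 0,
                       svm_config: SvmConfig = SvmConfig(),
                       select_k: int | None = None) -> MetricsReport:
    """Repeated stratified half-and-half validation.

    Each trial draws a fresh split with seed ``seed + trial``, fits the
    scaler and SVM on the training half and scores the held-out half. With
    ``features=None`` and ``select_k`` set, the feature subset is re-ranked
    inside each training half (leakage-free nested selection).
    """
    rows = [_one_trial(table, features, select_k, seed + t, svm_config)
            for t in range(n_trials)]
    return _aggregate(rows)


def half_and_half_ccr(table: pd.DataFrame, features: Sequence[str],
                      n_trials: int = 20, seed: int = 0,
                      svm_config: SvmConfig = SvmConfig()) -> float:
    """Mean half-and-half accuracy in percent (the CCR used during SFS)."""
    report = half_and_half_eval(table, features, n_trials=n_trials,
                                seed=seed, svm_config=svm_config)
    return report.mean["accuracy"]


def loocv_eval(table: pd.DataFrame, features: Sequence[str],
               svm_config: SvmConfig = SvmConfig()) -> MetricsReport:
    """Leave-one-out cross-validation with one pooled confusion matrix.

    Deterministic; reported as a single 'trial' with zero standard error.
    """
    labels = table["label"].to_numpy()
    if min(np.bincount(labels.astype(int))) < 2:
        raise ValueError("each class needs at least 2 cases")
    preds = np.empty(len(table), dtype=int)
    for i in range(len(table)):
        train = table.drop(table.index[i])
        test = table.iloc[[i]]
        scaler = fit_scaler(train, features)
        model = train_svm(apply_scaler(scaler, train), features, svm_config)
        preds[i] = predict(model, apply_scaler(scaler, test))[0]
    metrics = confusion_metrics(confusion_from_predictions(labels, preds))
    per_trial = pd.DataFrame([metrics])
    return MetricsReport(per_trial=per_trial, mean=dict(metrics),
                         se={m: 0.0 for m in METRICS}, n_trials=1,
                         n_undefined={m: int(not np.isfinite(metrics[m]))
                                      for m in METRICS})


def report_table(half: MetricsReport, loo: MetricsReport) -> str:
    """Side-by-side text table of the two validation protocols."""
    lines = [f"{'Parameter':<14}{'Half-and-half':>20}{'Leave-one-out':>18}"]
    names = {"accuracy": "Accuracy", "sensitivity": "Sensitivity",
             "specificity": "Specificity", "ppv": "PPV", "npv": "NPV"}
    for m in METRICS:
        h = f"{half.mean[m]:.2f} ± {half.se[m]:.2f}%"
        l = f"{loo.mean[m]:.2f}%"
        lines.append(f"{names[m]:<14}{h:>20}{l:>18}")
    return "\n".join(lines)
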