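"""SVM classification with deterministic preprocessing.

Features are z-scored with statistics estimated on the training rows only,
then fed to an RBF-kernel support vector machine (libsvm via scikit-learn).
Default hyperparameters are fixed — C = 1, gamma = 1 / n_features — so runs
are reproducible without tuning; an optional inner 5-fold grid search over
C in {2^-5 .. 2^15} and gamma in {2^-15 .. 2^3} (powers of 4) is available.

Labels: pancreatic cancer = 1 (positive class), chronic pancreatitis = 0.
A decision value of exactly 0 predicts class 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 0


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature center/scale fitted on training data.

    Zero-variance features get scale 1 and are listed in ``degenerate``.
    """

    center: pd.Series
    scale: pd.Series
    degenerate: tuple[str, ...] = ()


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"             # "rbf" or "linear"
    C: float = 1.0
    gamma: float | None = None      # None -> 1 / n_features
    grid_search: bool = False
    grid_folds: int = 5
    class_weight: str | dict | None = None


@dataclass
class SvmModel:
    """Fitted decision function plus the exact feature set it expects."""

    svc: SVC
    feature_names: tuple[str, ...]
    config: SvmConfig


def fit_scaler(train: pd.DataFrame,
               features: Sequence[str]) -> ScalerParams:
    """Estimate z-score parameters on the training table."""
    if len(train) == 0:
        raise ValueError("empty training table")
    x = train[list(features)].astype(float)
    center = x.mean()
    scale = x.std(ddof=0)
    degenerate = tuple(scale.index[scale <= 0.0])
    scale = scale.mask(scale <= 0.0, 1.0)
    return ScalerParams(center=center, scale=scale, degenerate=degenerate)


def apply_scaler(params: ScalerParams, table: pd.DataFrame) -> pd.DataFrame:
    """Z-score the feature columns; other columns pass through unchanged."""
    out = table.copy()
    feats = list(params.center.index)
    out[feats] = (table[feats].astype(float) - params.center) / params.scale
    return out


def _grid(config: SvmConfig) -> tuple[list[float], list[float]]:
    cs = [2.0 ** e for e in range(-5, 16, 2)]
    gammas = [2.0 ** e for e in range(-15, 4, 2)]
    return cs, gammas


def _make_svc(config: SvmConfig, C: float, gamma: float) -> SVC:
    kwargs = dict(C=C, class_weight=config.class_weight, cache_size=64)
    if config.kernel == "rbf":
        return SVC(kernel="rbf", gamma=gamma, **kwargs)
    if config.kernel == "linear":
        return SVC(kernel="linear", **kwargs)
    raise ValueError(f"unsupported kernel {config.kernel!r}")


def train_svm(train: pd.DataFrame, features: Sequence[str],
              config: SvmConfig = SvmConfig()) -> SvmModel:
    """Fit the SVM on already-scaled training features.

    Deterministic given the configuration and the row order of ``train``.
    """
    features = tuple(features)
    x = train[list(features)].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    gamma = config.gamma if config.gamma is not None else 1.0 / len(features)
    C = config.C
    if config.grid_search:
        C, gamma = _grid_search(x, y, config)
    svc = _make_svc(config, C, gamma)
    svc.fit(x, y)
    return SvmModel(svc=svc, feature_names=features, config=config)


def _grid_search(x: np.ndarray, y: np.ndarray,
                 config: SvmConfig) -> tuple[float, float]:
    """Inner stratified k-fold CCR maximization; ties favor smaller C, gamma."""
    cs, gammas = _grid(config)
    folds = StratifiedKFold(n_splits=config.grid_folds, shuffle=False)
    best = (-1.0, 0.0, 0.0)
    for C in cs:
        for gamma in gammas:
            correct = 0
            for tr, te in folds.split(x, y):
                svc = _make_svc(config, C, gamma)
                svc.fit(x[tr], y[tr])
                correct += int((_decide(svc, x[te]) == y[te]).sum())
            ccr = correct / len(y)
            if ccr > best[0]:
                best = (ccr, C, gamma)
    return best[1], best[2]


def _decide(svc: SVC, x: np.ndarray) -> np.ndarray:
    """Labels from the decision function; decision value 0 -> class 0."""
    return np.where(svc.decision_function(x) > 0.0,
                    POSITIVE_LABEL, NEGATIVE_LABEL)


def decision_values(model: SvmModel, table: pd.DataFrame) -> np.ndarray:
    _check_features(model, table)
    return model.svc.decision_function(
        table[list(model.feature_names)].to_numpy(dtype=float))


def predict(model: SvmModel, table: pd.DataFrame) -> np.ndarray:
    """One label per row (cancer = 1, pancreatitis = 0)."""
    _check_features(model, table)
    return _decide(model.svc,
                   table[list(model.feature_names)].to_numpy(dtype=float))


def _check_features(model: SvmModel, table: pd.DataFrame) -> None:
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks model features: {missing}")
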