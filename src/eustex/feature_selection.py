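"""Two-stage feature selection: class-distance ranking, then an SFS curve.

Stage 1 ranks every feature by a robust separation score between the two
diagnostic classes — the absolute gap between class medians normalized by
the summed median absolute deviations — and keeps the top ``m`` (25 by
default). Stage 2 adds the ranked features one by one and scores each prefix
by the correct-classification rate (CCR) of the SVM under repeated
stratified half-and-half validation; the optimum subset size is the CCR
argmax (smallest size on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import SvmConfig
from .texture_features import feature_columns

_EPS = 1e-12


@dataclass(frozen=True)
class ClassDistanceRanking:
    """Per-feature separation scores and the descending-score order."""

    scores: dict[str, float]
    order: tuple[str, ...]          # permutation of all scored features
    m: int                          # size of the retained head

    @property
    def selected(self) -> tuple[str, ...]:
        return self.order[:self.m]


@dataclass(frozen=True)
class SfsStep:
    k: int
    feature_added: str
    ccr: float                      # percent


@dataclass(frozen=True)
class SfsTrace:
    """CCR-versus-subset-size record of the forward-selection sweep."""

    steps: tuple[SfsStep, ...]
    optimum_k: int
    optimum_ccr: float

    @property
    def ccr_by_k(self) -> list[float]:
        return [s.ccr for s in self.steps]

    def features_at(self, k: int) -> list[str]:
        return [s.feature_added for s in self.steps[:k]]

    @property
    def optimum_features(self) -> list[str]:
        return self.features_at(self.optimum_k)


@dataclass(frozen=True)
class SfsConfig:
    """Evaluation protocol used to score candidate subsets."""

    n_trials: int = 20
    seed: int = 202
    svm: SvmConfig = field(default_factory=SvmConfig)
    mode: str = "ranked"            # "ranked" (default) or "greedy"


def class_distance(values_a: Sequence[float],
                   values_b: Sequence[float]) -> float:
    """MAD-normalized gap between class medians.

    ``d = |median(a) - median(b)| / (MAD(a) + MAD(b) + eps)`` where MAD is
    the median absolute deviation from the class median. Symmetric,
    translation- and scale-invariant, and 0 iff the medians coincide.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least 2 values")
    med_a, med_b = np.median(a), np.median(b)
    mad_a = np.median(np.abs(a - med_a))
    mad_b = np.median(np.abs(b - med_b))
    return float(abs(med_a - med_b) / (mad_a + mad_b + _EPS))


def rank_features(table: pd.DataFrame, m: int = 25) -> ClassDistanceRanking:
    """Class-distance score for every feature; keep the ``m`` highest.

    Ties are broken by canonical (column) order, so the ranking is invariant
    to the row order of the cohort table.
    """
    feats = feature_columns(table)
    if m > len(feats):
        raise ValueError(f"m={m} exceeds the {len(feats)} available features")
    labels = table["label"].to_numpy()
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("table must contain both classes (labels 0 and 1)")
    pos, neg = table[labels == 1], table[labels == 0]
    scores = {f: class_distance(pos[f], neg[f]) for f in feats}
    # stable sort on descending score keeps canonical order among ties
    order = tuple(sorted(feats, key=lambda f: -scores[f]))
    return ClassDistanceRanking(scores=scores, order=order, m=m)


def curve_optimum(ccr_by_k: Sequence[float]) -> tuple[int, float]:
    """Argmax of a CCR-versus-subset-size curve; 1-based, smallest k on ties."""
    ccr = list(ccr_by_k)
    if not ccr:
        raise ValueError("empty CCR curve")
    if min(ccr) < 0 or max(ccr) > 100:
        raise ValueError("CCR values must be percentages in [0, 100]")
    best = max(ccr)
    return ccr.index(best) + 1, best


def sfs_curve(table: pd.DataFrame, ranked: ClassDistanceRanking,
              config: SfsConfig = SfsConfig()) -> SfsTrace:
    """Score growing feature subsets by half-and-half CCR.

    In the default ``ranked`` mode the k-th subset is simply the first k
    ranked features (the set at step k is a superset of step k-1). The
    optional ``greedy`` mode is classic SFS: each step adds whichever
    remaining candidate maximizes CCR (ties: ranking order).
    """
    from .evaluation import half_and_half_ccr   # late import: avoid cycle

    candidates = list(ranked.selected)
    if not candidates:
        raise ValueError("empty candidate ranking")
    steps: list[SfsStep] = []
    if config.mode == "ranked":
        for k in range(1, len(candidates) + 1):
            ccr = half_and_half_ccr(table, candidates[:k],
                                    n_trials=config.n_trials,
                                    seed=config.seed, svm_config=config.svm)
            steps.append(SfsStep(k=k, feature_added=candidates[k - 1], ccr=ccr))
    elif config.mode == "greedy":
        chosen: list[str] = []
        remaining = list(candidates)
        while remaining:
            scored = [(half_and_half_ccr(table, chosen + [c],
                                         n_trials=config.n_trials,
                                         seed=config.seed,
                                         svm_config=config.svm), c)
                      for c in remaining]
            best_ccr = max(s for s, _ in scored)
            best_feat = next(c for s, c in scored if s == best_ccr)
            chosen.append(best_feat)
            remaining.remove(best_feat)
            steps.append(SfsStep(k=len(chosen), feature_added=best_feat,
                                 ccr=best_ccr))
    else:
        raise ValueError(f"unknown SFS mode {config.mode!r}")
    k_star, ccr_star = curve_optimum([s.ccr for s in steps])
    return SfsTrace(steps=tuple(steps), optimum_k=k_star, optimum_ccr=ccr_star)


def trace_to_frame(trace: SfsTrace) -> pd.DataFrame:
    """Tabular view of an SFS trace (one row per subset size)."""
    return pd.DataFrame({"k": [s.k for s in trace.steps],
                         "feature_added": [s.feature_added for s in trace.steps],
                         "ccr": [s.ccr for s in trace.steps]})
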