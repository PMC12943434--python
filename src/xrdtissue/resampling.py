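"""Patient-level bootstrap confidence intervals and permutation tests.

All inference here operates on the patient score table (one out-of-fold
probability and one label per patient), which is the unit of independence
in the study design.  The bootstrap resamples N patients with replacement
(2000 resamples by default) and reports percentile 95% intervals for AUC
and AP plus a pointwise ROC envelope on a fixed false-positive-rate grid.
The permutation test shuffles patient labels with the scores held fixed
(10,000 shuffles by default) and uses the add-one estimator
``p = (1 + #{null >= observed}) / (1 + n_permutations)`` so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import POSITIVE_LABEL

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "auc_score",
    "ap_score",
    "patient_bootstrap",
    "permutation_test",
    "bootstrap_operating_point",
]


def auc_score(y: np.ndarray, s: np.ndarray) -> float:
    """Rank-statistic ROC AUC with half-credit for tied scores."""
    y = np.asarray(y, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(s)  # average ranks: ties get half credit
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def ap_score(y: np.ndarray, s: np.ndarray) -> float:
    """Average precision: step sum over descending-score ranks, equal
    scores grouped into one threshold step."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("at least one positive required for AP")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    k = np.arange(1, y.size + 1)
    # evaluate only at the last index of each tied-score block
    block_end = np.ones(y.size, dtype=bool)
    block_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    recall = tp[block_end] / n_pos
    precision = tp[block_end] / k[block_end]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def _roc_points(y: np.ndarray, s: np.ndarray):
    """(fpr, tpr) swept over distinct thresholds, anchored at (0,0)."""
    order = np.argsort(-s, kind="mergesort")
    y_sorted = np.asarray(y, dtype=float)[order]
    s_sorted = np.asarray(s, dtype=float)[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    block_end = np.ones(y_sorted.size, dtype=bool)
    block_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    tpr = np.concatenate([[0.0], tp[block_end] / tp[-1]])
    fpr = np.concatenate([[0.0], fp[block_end] / fp[-1]])
    return fpr, tpr


@dataclass
class BootstrapResult:
    """Percentile bootstrap summary at the patient level."""

    auc: float
    ap: float
    auc_ci: tuple[float, float]
    ap_ci: tuple[float, float]
    fpr_grid: np.ndarray
    roc_envelope: tuple[np.ndarray, np.ndarray]  # (lower TPR, upper TPR)
    B: int
    seed: int
    n_redrawn: int


@dataclass
class PermutationResult:
    """Add-one permutation p-values for AUC and AP."""

    p_value_auc: float
    p_value_ap: float
    observed_auc: float
    observed_ap: float
    n_permutations: int
    seed: int


def _score_arrays(scores: pd.DataFrame, positive_label: str):
    y = (scores["label"] == positive_label).to_numpy()
    s = scores["score"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return y, s


def patient_bootstrap(
    scores: pd.DataFrame,
    B: int = 2000,
    fpr_grid: np.ndarray | None = None,
    seed: int = 0,
    positive_label: str = POSITIVE_LABEL,
) -> BootstrapResult:
    """Patient-level percentile bootstrap of AUC, AP and the ROC envelope.

    Each resample draws N patients with replacement; resamples containing a
    single class are redrawn (their count is reported).  Per-resample ROC
    curves are linearly interpolated onto ``fpr_grid`` (default: 101 evenly
    spaced points on [0, 1]) and the pointwise 2.5th/97.5th percentiles
    form the 95% envelope.
    """
    y, s = _score_arrays(scores, positive_label)
    if min(int(y.sum()), int((~y).sum())) < 2:
        raise ValueError("need >= 2 patients per class to bootstrap")
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentiles")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    fpr_grid = np.asarray(fpr_grid, dtype=float)

    rng = np.random.default_rng(seed)
    n = y.size
    aucs = np.empty(B)
    aps = np.empty(B)
    tprs = np.empty((B, fpr_grid.size))
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            n_redrawn += 1
        sb = s[idx]
        aucs[b] = auc_score(yb, sb)
        aps[b] = ap_score(yb, sb)
        fpr_b, tpr_b = _roc_points(yb, sb)
        tprs[b] = np.interp(fpr_grid, fpr_b, tpr_b)
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} single-class bootstrap resamples")
    lo, hi = np.percentile(tprs, [2.5, 97.5], axis=0)
    return BootstrapResult(
        auc=auc_score(y, s),
        ap=ap_score(y, s),
        auc_ci=tuple(np.percentile(aucs, [2.5, 97.5])),
        ap_ci=tuple(np.percentile(aps, [2.5, 97.5])),
        fpr_grid=fpr_grid,
        roc_envelope=(lo, hi),
        B=B,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def permutation_test(
    scores: pd.DataFrame,
    n_permutations: int = 10000,
    seed: int = 0,
    positive_label: str = POSITIVE_LABEL,
) -> PermutationResult:
    """Label-shuffle null for AUC and AP with the scores held fixed."""
    y, s = _score_arrays(scores, positive_label)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed_auc = auc_score(y, s)
    observed_ap = ap_score(y, s)

    rng = np.random.default_rng(seed)
    n = y.size
    n_pos = int(y.sum())

    # AUC null, vectorized through the rank-sum statistic
    ranks = rankdata(s)
    perm = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_pos]
    rank_sums = ranks[perm].sum(axis=1)
    null_auc = (rank_sums - n_pos * (n_pos + 1) / 2.0) / (n_pos * (n - n_pos))

    # AP null, vectorized over the fixed descending-score order
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    block_end = np.ones(n, dtype=bool)
    block_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    k = np.arange(1, n + 1)
    y_perm = np.zeros((n_permutations, n))
    np.put_along_axis(y_perm, perm, 1.0, axis=1)
    y_perm_sorted = y_perm[:, order]
    tp = np.cumsum(y_perm_sorted, axis=1)
    recall = tp[:, block_end] / n_pos
    precision = tp[:, block_end] / k[block_end]
    prev = np.concatenate([np.zeros((n_permutations, 1)), recall[:, :-1]], axis=1)
    null_ap = np.sum((recall - prev) * precision, axis=1)

    p_auc = (1.0 + np.sum(null_auc >= observed_auc)) / (1.0 + n_permutations)
    p_ap = (1.0 + np.sum(null_ap >= observed_ap)) / (1.0 + n_permutations)
    return PermutationResult(
        p_value_auc=float(p_auc),
        p_value_ap=float(p_ap),
        observed_auc=observed_auc,
        observed_ap=observed_ap,
        n_permutations=n_permutations,
        seed=seed,
    )


def bootstrap_operating_point(
    scores: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    positive_label: str = POSITIVE_LABEL,
) -> dict:
    """Percentile 95% intervals for Youden-point sensitivity/specificity."""
    y, s = _score_arrays(scores, positive_label)
    rng = np.random.default_rng(seed)
    n = y.size
    sens = np.empty(B)
    spec = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        fpr, tpr = _roc_points(y[idx], s[idx])
        j = tpr - fpr
        best = int(np.argmax(j))
        sens[b], spec[b] = tpr[best], 1.0 - fpr[best]
    return {
        "sensitivity_ci": tuple(np.percentile(sens, [2.5, 97.5])),
        "specificity_ci": tuple(np.percentile(spec, [2.5, 97.5])),
        "B": B,
        "seed": seed,
    }
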