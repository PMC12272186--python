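"""Evaluation metrics for map comparison and group analysis.

MWF errors are always reported in *percentage points* of the myelin water
fraction (an estimate of 0.12 vs truth 0.10 is a 2.0 pp error), never in
relative percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparisonReport", "compare_maps", "roc_auc", "group_compare"]


@dataclass(frozen=True)
class ComparisonReport:
    """Agreement metrics between an estimated and a reference map."""

    mae: float  # mean absolute error, percentage points
    rmsd: float  # root mean square difference, percentage points
    pearson_r: float  # NaN when either vector is constant
    bland_altman_mean: float  # mean difference, percentage points
    bland_altman_loa: tuple[float, float]  # mean +/- 1.96 SD
    n: int


def compare_maps(
    estimate: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    scale: float = 100.0,
) -> ComparisonReport:
    """Compare two maps over a mask.

    ``scale`` converts fractions to percentage points (default 100); pass 1
    for quantities already in the reporting unit (e.g. B1+ in percent).
    """
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("map shapes differ")
    if mask is None:
        mask = np.isfinite(estimate) & np.isfinite(truth)
    else:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
    e = estimate[mask] * scale
    t = truth[mask] * scale
    diff = e - t
    mae = float(np.mean(np.abs(diff)))
    rmsd = float(np.sqrt(np.mean(diff**2)))
    if len(e) >= 2 and np.std(e) > 0 and np.std(t) > 0:
        r = float(stats.pearsonr(e, t).statistic)
    else:
        r = float("nan")
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    loa = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    return ComparisonReport(
        mae=mae, rmsd=rmsd, pearson_r=r, bland_altman_mean=mean_diff,
        bland_altman_loa=loa, n=int(len(e)),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic.

    AUC = P(score_positive > score_negative), ties counted 1/2 -- the
    Mann-Whitney U statistic over n_pos * n_neg pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_tests: int = 1,
    alpha: float = 0.001,
    equal_var: bool = True,
) -> tuple[float, float, bool]:
    """Two-tailed unpaired t-test with Bonferroni-adjusted significance.

    Returns ``(t, p, significant)`` where significance is assessed at
    ``alpha / n_tests``.  The pooled-variance test is the default
    ("unpaired t-test"); set ``equal_var=False`` for Welch.  With zero
    variance in both groups and equal means the statistic is undefined and
    ``(nan, nan, False)`` is returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return float("nan"), float("nan"), False
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, bool(np.isfinite(p) and p < alpha / n_tests)
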