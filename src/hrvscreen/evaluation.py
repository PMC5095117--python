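"""Diagnostic-performance statistics for the screening scores.

AUC is the Mann-Whitney probability that a random depressed subject scores
above a random healthy one (ties counted half), with a Hanley-McNeil 95%
confidence interval; the operating cutoff maximizes Youden's J
(sensitivity + specificity - 1).  A cutoff c calls a subject positive when
score >= c.  Group contrasts use Student's pooled t-test and the logit-SDS
association uses the Pearson correlation, matching standard screening
methodology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import FEATURE_NAMES, SubjectRecord

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "roc",
    "youden_cutoff",
    "confusion",
    "sds_screen",
    "compare_groups",
    "correlate_sds",
]

SDS_RANGE = (20, 80)


@dataclass
class ROCResult:
    """Threshold-sweep ROC curve with AUC, CI and the Youden cutoff."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci95: tuple[float, float]
    optimal_cutoff: float
    youden_j: float


@dataclass
class ConfusionMetrics:
    """Confusion counts with the four screening percentages.

    Percentages are exact fractions times 100; use :meth:`rounded` for the
    one-decimal reporting convention.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn)

    def rounded(self) -> dict[str, float]:
        return {
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
            "ppv": round(self.ppv, 1),
            "npv": round(self.npv, 1),
        }


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(
        [1 if v in (1, True, "MDD") else 0 if v in (0, False, "healthy") else v
         for v in np.asarray(labels).ravel()]
    ).astype(float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary (0/1 or healthy/MDD)")
    return y.astype(int)


def _mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    r1 = ranks[y == 1].sum()
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _hanley_mcneil_ci(auc: float, n1: int, n0: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    se = np.sqrt(max(var, 0.0))
    return (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))


def roc(scores, labels) -> ROCResult:
    """ROC curve over all distinct score thresholds, AUC and Youden cutoff."""
    s = np.asarray(scores, dtype=float).ravel()
    y = _as_binary(labels)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    # thresholds: +inf, then distinct scores descending; positive iff s >= c
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        pos = s >= c
        tpr[i] = np.count_nonzero(pos & (y == 1)) / n1
        fpr[i] = np.count_nonzero(pos & (y == 0)) / n0

    auc = _mann_whitney_auc(s, y)
    cutoff, j = _youden_scan(s, y)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=float(auc),
        ci95=_hanley_mcneil_ci(float(auc), n1, n0),
        optimal_cutoff=cutoff,
        youden_j=j,
    )


def _youden_scan(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    best_c, best_j = np.inf, -np.inf
    for c in np.unique(s):
        pos = s >= c
        sens = np.count_nonzero(pos & (y == 1)) / max(1, int(y.sum()))
        spec = np.count_nonzero(~pos & (y == 0)) / max(1, int((1 - y).sum()))
        j = sens + spec - 1.0
        # ties broken toward the lower cutoff (higher sensitivity)
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and c < best_c):
            best_j, best_c = j, float(c)
    return best_c, float(best_j)


def youden_cutoff(roc_result: ROCResult | None, scores, labels) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate cutoffs are the distinct observed scores (positive when
    score >= cutoff); ties go to the lower cutoff.  Warns when even the
    best cutoff is uninformative (J <= 0).
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = _as_binary(labels)
    cutoff, j = _youden_scan(s, y)
    if j <= 0:
        warnings.warn(
            f"anti-informative scores: best Youden J = {j:.3f}", stacklevel=2
        )
    return cutoff


def confusion(labels, predicted) -> ConfusionMetrics:
    """Confusion counts of predicted vs true labels (positive = depressed)."""
    y = _as_binary(labels)
    yhat = _as_binary(predicted)
    if y.size != yhat.size:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionMetrics(
        tp=int(np.count_nonzero((y == 1) & (yhat == 1))),
        fn=int(np.count_nonzero((y == 1) & (yhat == 0))),
        tn=int(np.count_nonzero((y == 0) & (yhat == 0))),
        fp=int(np.count_nonzero((y == 0) & (yhat == 1))),
    )


def sds_screen(sds_scores, cutoff: int = 50) -> np.ndarray:
    """Subjective screen: depressed when the SDS score >= cutoff."""
    s = np.asarray(sds_scores, dtype=float).ravel()
    if np.any((s < SDS_RANGE[0]) | (s > SDS_RANGE[1])):
        bad = s[(s < SDS_RANGE[0]) | (s > SDS_RANGE[1])][0]
        raise ValueError(f"SDS score {bad:g} outside scale range {SDS_RANGE}")
    return (s >= cutoff).astype(int)


def compare_groups(records: list[SubjectRecord], equal_var: bool = True) -> pd.DataFrame:
    """Per-feature two-sample t-test between depressed and healthy groups.

    Student's pooled-variance t by default (Welch via ``equal_var=False``).
    Returns a table with group means, t and the two-sided p per feature.
    """
    mdd = [r for r in records if r.diagnosis == "MDD"]
    hea = [r for r in records if r.diagnosis == "healthy"]
    if len(mdd) < 2 or len(hea) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for name in FEATURE_NAMES:
        a = np.array([getattr(r.features, name) for r in mdd])
        b = np.array([getattr(r.features, name) for r in hea])
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "feature": name,
                "mean_mdd": a.mean(),
                "mean_healthy": b.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def correlate_sds(logits, sds) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between logit and SDS scores."""
    x = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(sds, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in logits or SDS scores")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
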