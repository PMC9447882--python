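"""Per-class sensitivities and AUROC with a DeLong confidence interval.

On a heavily imbalanced outcome (~4% favorable) overall accuracy and AUROC
alone hide the minority class, so the primary operating metric here is the
pair of per-class sensitivities and their unweighted mean.  AUROC is the
Mann-Whitney rank statistic; its 95% CI uses DeLong's structural-component
variance estimate (deterministic, no resampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["MetricsReport", "MetricsError", "auroc_rank", "delong_ci", "metrics_report"]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsReport:
    sensitivity_pos: float
    sensitivity_neg: float
    average_class_sensitivity: float
    auroc: float
    auroc_ci: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int
    threshold: float

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["auroc_ci"] = list(self.auroc_ci)
        return d


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(bool)
    if not y.any() or y.all():
        raise MetricsError("labels contain a single class; AUROC is undefined")
    return y


def auroc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUROC as the Mann-Whitney statistic with midranks for ties."""
    y = _check_labels(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _structural_components(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong V10/V01 placement components and the AUC."""
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa, with ties at 1/2
    v10 = np.empty(m)
    order = np.sort(neg)
    lt = np.searchsorted(order, pos, side="left")
    le = np.searchsorted(order, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n
    order_p = np.sort(pos)
    lt = np.searchsorted(order_p, neg, side="left")
    le = np.searchsorted(order_p, neg, side="right")
    v01 = 1.0 - (lt + 0.5 * (le - lt)) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_ci(scores: np.ndarray, y: np.ndarray, level: float = 0.95
              ) -> tuple[float, tuple[float, float]]:
    """AUROC and its DeLong Wald confidence interval, clipped to [0, 1]."""
    y = _check_labels(y)
    scores = np.asarray(scores, dtype=float)
    v10, v01, auc = _structural_components(scores, y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return auc, (min(lo, auc), max(hi, auc))


def metrics_report(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Thresholded per-class sensitivities plus rank AUROC with DeLong CI."""
    y = _check_labels(y)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != y.shape:
        raise MetricsError("scores and labels length mismatch")
    pred = scores >= threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    auc, ci = delong_ci(scores, y)
    return MetricsReport(
        sensitivity_pos=tp / (tp + fn),
        sensitivity_neg=tn / (tn + fp),
        average_class_sensitivity=0.5 * (tp / (tp + fn) + tn / (tn + fp)),
        auroc=auc,
        auroc_ci=ci,
        tp=tp, fn=fn, tn=tn, fp=fp,
        threshold=threshold,
    )
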