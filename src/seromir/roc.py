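"""ROC analysis and confusion-matrix metrics for diagnostic scores.

The ROC sweep uses the same strict-">" convention as risk-score
classification: at threshold t a sample is called positive iff its score
exceeds t. AUC is the trapezoidal area, equal to the Mann-Whitney
probability that a random case outscores a random control with ties
half-credited. The operating cutoff is the threshold maximizing
sensitivity + specificity (ties broken toward higher specificity, then
higher threshold). Confidence intervals come from a class-stratified
percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 classification counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("empty confusion table")

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        yhat = np.asarray(predicted, dtype=int)
        if y.shape != yhat.shape:
            raise ValueError("labels and predictions must align")
        return cls(
            tp=int(np.sum((y == 1) & (yhat == 1))),
            fp=int(np.sum((y == 0) & (yhat == 1))),
            tn=int(np.sum((y == 0) & (yhat == 0))),
            fn=int(np.sum((y == 1) & (yhat == 0))),
        )


def _ratio_pct(num: int, den: int) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV as percentages.

    A metric with a zero denominator is reported as NaN (undefined),
    never as 0.
    """
    return {
        "sensitivity": _ratio_pct(c.tp, c.tp + c.fn),
        "specificity": _ratio_pct(c.tn, c.tn + c.fp),
        "ppv": _ratio_pct(c.tp, c.tp + c.fp),
        "npv": _ratio_pct(c.tn, c.tn + c.fn),
    }


@dataclass
class ROCResult:
    """Threshold sweep with AUC, optional bootstrap CI, and the
    sensitivity+specificity-optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci: Optional[tuple[float, float]]
    optimal_cutoff: float
    sensitivity_at_optimum: float
    specificity_at_optimum: float

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d arrays")
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    if not set(np.unique(y)) == {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    return s, y


def roc_curve(scores, labels, ci=None) -> ROCResult:
    """Full ROC sweep over the unique score values plus a -inf sentinel
    (the classify-everything-positive point)."""
    s, y = _check_scores_labels(scores, labels)
    thresholds = np.concatenate(([-np.inf], np.unique(s)))
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s > t
        sens[i] = np.sum(pred & (y == 1)) / n_pos
        spec[i] = np.sum(~pred & (y == 0)) / n_neg
    # trapezoid over the ROC polygon; thresholds ascend so FPR descends
    fpr = 1.0 - spec
    auc = float(-np.trapezoid(sens, fpr))
    cutoff, opt_sens, opt_spec = _best_threshold(thresholds, sens, spec)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci=ci,
        optimal_cutoff=cutoff,
        sensitivity_at_optimum=opt_sens,
        specificity_at_optimum=opt_spec,
    )


def _best_threshold(thresholds, sens, spec) -> tuple[float, float, float]:
    total = sens + spec
    best = 0
    for i in range(1, len(thresholds)):
        if total[i] > total[best] + 1e-12:
            best = i
        elif abs(total[i] - total[best]) <= 1e-12:
            if spec[i] > spec[best] + 1e-12 or (
                abs(spec[i] - spec[best]) <= 1e-12 and thresholds[i] > thresholds[best]
            ):
                best = i
    return float(thresholds[best]), float(sens[best]), float(spec[best])


def optimal_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity; ties broken by
    higher specificity, then higher threshold."""
    return _best_threshold(roc.thresholds, roc.sensitivity, roc.specificity)


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    # rank formulation; average ranks give ties half credit
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_ci(
    scores, labels, n_boot: int = 2000, seed: int | None = None
) -> tuple[float, float]:
    """95% percentile bootstrap CI for the AUC, resampling cases and
    controls separately (class-stratified). ``seed`` is required for a
    reproducible interval."""
    if seed is None:
        raise ValueError("seed is required for a reproducible bootstrap")
    s, y = _check_scores_labels(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each class needs >= 2 members for the bootstrap")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        bs = np.concatenate([bp, bn])
        by = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
        aucs[b] = _auc_mann_whitney(bs, by)
    low, high = np.quantile(aucs, [0.025, 0.975])
    return float(low), float(high)
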