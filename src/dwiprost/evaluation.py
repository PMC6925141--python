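"""ROC/AUC evaluation with bootstrap confidence intervals.

AUC is the Mann-Whitney concordance probability (ties count one half):
the chance a randomly chosen positive subject scores above a randomly
chosen negative one. Confidence intervals are percentile bootstrap over
the natural resampling unit — patients at patient level, slices at slice
level — and AUC differences between two scorers of the same subjects are
tested by a paired bootstrap of the difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    level: str = "slice"
    n: int = 0

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "level": self.level, "n": self.n}


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int],
            level: str = "slice") -> ROCResult:
    """ROC curve and AUC (trapezoidal == pairwise concordance with ties 1/2)."""
    scores, labels = _check(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auc=float(roc_auc_score(labels, scores)),
                     level=level, n=len(labels))


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    max_retries: int = 100,
) -> Tuple[float, float]:
    """Percentile-bootstrap 95% (by default) CI for the AUC.

    Units are resampled with replacement; a resample that loses one of
    the classes is redrawn (up to ``max_retries`` times per replicate).
    """
    scores, labels = _check(scores, labels)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(labels)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries):
            idx = rng.integers(0, n, n)
            if 0 < labels[idx].sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def evaluate(scores, labels, level: str = "slice", n_boot: int = 2000,
             alpha: float = 0.05, seed: int = 0) -> ROCResult:
    """ROC/AUC plus bootstrap CI in one call."""
    res = roc_auc(scores, labels, level=level)
    res.ci_low, res.ci_high = bootstrap_ci(scores, labels, n_boot=n_boot,
                                           alpha=alpha, seed=seed)
    return res


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-tailed p-value for AUC(a) != AUC(b) by paired bootstrap.

    Both scorers must score the same subjects. Subjects are resampled
    jointly; the p-value is twice the smaller tail mass of the bootstrap
    distribution of the AUC difference around zero, capped at 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    _, labels = _check(scores_a, labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("scores_a and scores_b must have equal length")
    rng = np.random.default_rng(seed)
    n = len(labels)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            if 0 < labels[idx].sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        deltas[b] = (roc_auc_score(labels[idx], scores_a[idx])
                     - roc_auc_score(labels[idx], scores_b[idx]))
    p_low = np.mean(deltas <= 0)
    p_high = np.mean(deltas >= 0)
    return float(min(1.0, 2.0 * min(p_low, p_high)))
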