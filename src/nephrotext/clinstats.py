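"""Biomarker diagnostics: ROC, Youden cutoff, 2x2 predictive values, odds ratio.

The surface a clinical reader expects from a continuous biomarker (here the
platelet-to-albumin ratio against severe glomerular lesions): the empirical
ROC curve with its area, the Youden-index-optimal cutoff, the confusion
matrix at that cutoff with sensitivity/specificity/PPV/NPV, and the
unadjusted 2x2 odds ratio with a Wald confidence interval.

The ROC is computed from first principles — candidate thresholds are the
midpoints between adjacent sorted unique scores plus -inf/+inf sentinels, a
score counts as a positive call when it is >= the threshold — because the
threshold set is part of the contract (the Youden cutoff is reported as a
usable decision value).  The trapezoidal area is checked against the
Mann-Whitney rank statistic, to which it is mathematically identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, UndefinedMetricError

__all__ = [
    "Confusion2x2",
    "RocResult",
    "roc",
    "youden_cutoff",
    "confusion_metrics",
    "odds_ratio",
    "bootstrap_auc_ci",
]


@dataclass(frozen=True)
class Confusion2x2:
    """2x2 diagnostic table: test positive/negative vs disease present/absent."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion-matrix cells must be nonnegative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise DomainError("confusion matrix is empty")

    @classmethod
    def from_scores(cls, scores, labels, cutoff: float) -> "Confusion2x2":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        pos = scores >= cutoff
        return cls(tp=int(np.sum(pos & (labels == 1))),
                   fp=int(np.sum(pos & (labels == 0))),
                   fn=int(np.sum(~pos & (labels == 1))),
                   tn=int(np.sum(~pos & (labels == 0))))


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC: thresholds with paired sensitivity/specificity, AUC,
    the Youden-optimal cutoff, and whether scores were sign-flipped."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    optimal_cutoff: float
    youden_j: float
    flipped: bool = False


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc(scores, labels) -> RocResult:
    """Empirical ROC of ``scores`` against binary ``labels`` (1 = diseased).

    Higher scores are assumed to indicate disease; if the data violate that
    (trapezoidal AUC < 0.5), scores are negated with a warning and the
    returned cutoff applies to the negated scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be aligned 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC requires both classes present")

    def curve(s):
        uniq = np.unique(s)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
        n_pos = int(np.sum(labels == 1))
        n_neg = int(np.sum(labels == 0))
        sens = np.array([np.sum((s >= t) & (labels == 1)) / n_pos for t in thresholds])
        spec = np.array([np.sum((s < t) & (labels == 0)) / n_neg for t in thresholds])
        # trapezoid over the ROC staircase, corners included: lexicographic
        # (fpr, sens) order so vertical climbs precede horizontal moves
        fpr = 1.0 - spec
        order = np.lexsort((sens, fpr))
        area = float(np.trapezoid(sens[order], fpr[order]))
        return thresholds, sens, spec, area

    thresholds, sens, spec, area = curve(scores)
    flipped = False
    if area < 0.5:
        warnings.warn("scores are inversely related to the outcome; flipping sign",
                      stacklevel=2)
        scores = -scores
        thresholds, sens, spec, area = curve(scores)
        flipped = True

    rank_area = _rank_auc(scores, labels)
    if abs(area - rank_area) > 1e-10:
        raise AssertionError(
            f"trapezoidal AUC {area} disagrees with rank-statistic AUC {rank_area}")

    result = RocResult(thresholds=thresholds, sensitivities=sens,
                       specificities=spec, auc=area, optimal_cutoff=np.nan,
                       youden_j=np.nan, flipped=flipped)
    cutoff = youden_cutoff(result)
    i = int(np.flatnonzero(result.thresholds == cutoff)[0])
    return RocResult(thresholds=thresholds, sensitivities=sens, specificities=spec,
                     auc=area, optimal_cutoff=cutoff,
                     youden_j=float(sens[i] + spec[i] - 1.0), flipped=flipped)


def youden_cutoff(roc_result: RocResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the lower
    threshold.
    """
    j = roc_result.sensitivities + roc_result.specificities - 1.0
    best = j.max()
    candidates = np.flatnonzero(np.isclose(j, best, rtol=0, atol=1e-12))
    spec_at = roc_result.specificities[candidates]
    candidates = candidates[np.isclose(spec_at, spec_at.max(), rtol=0, atol=1e-12)]
    return float(np.min(roc_result.thresholds[candidates]))


def confusion_metrics(cm: Confusion2x2) -> dict:
    """Sensitivity, specificity, PPV and NPV from a 2x2 table.

    A metric whose denominator is zero is reported as None together with an
    entry in the ``undefined`` list, rather than raising.
    """
    out: dict = {"undefined": []}
    for name, num, den in (
        ("sensitivity", cm.tp, cm.tp + cm.fn),
        ("specificity", cm.tn, cm.tn + cm.fp),
        ("ppv", cm.tp, cm.tp + cm.fp),
        ("npv", cm.tn, cm.tn + cm.fn),
    ):
        if den == 0:
            out[name] = None
            out["undefined"].append(name)
        else:
            out[name] = num / den
    return out


def odds_ratio(cm: Confusion2x2, ci_level: float = 0.95) -> dict:
    """Unadjusted 2x2 odds ratio with a Wald (log-scale) confidence interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.
    """
    a, b, c, d = cm.tp, cm.fp, cm.fn, cm.tn
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = np.exp(np.log(oratio) - z * se), np.exp(np.log(oratio) + z * se)
    return {"odds_ratio": float(oratio), "ci_low": float(lo), "ci_high": float(hi),
            "ci_level": ci_level, "haldane_corrected": corrected}


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                     ci_level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the ROC AUC (resampling patients)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = []
    while len(aucs) < n_boot:
        idx = rng.integers(n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        aucs.append(_rank_auc(scores[idx], labels[idx]))
    lo = (1.0 - ci_level) / 2.0
    return (float(np.quantile(aucs, lo)), float(np.quantile(aucs, 1.0 - lo)))
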