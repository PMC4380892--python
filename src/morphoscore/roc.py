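"""ROC analysis for the Sc score: curve, AUC with DeLong CI, and the
minimal-sum-of-squared-coordinates cut-off.

Conventions: higher score predicts blastocyst formation; an embryo is called
positive when ``score >= threshold``.  Thresholds are the midpoints between
consecutive distinct scores plus one sentinel below the minimum and one above
the maximum, so the evaluated operating points are exactly the attainable
confusion matrices.  The trapezoidal AUC over that grid equals the
tie-adjusted Mann–Whitney probability U/(n1*n0).

The cut-off minimises (1 - sensitivity)^2 + (1 - specificity)^2 — the
operating point closest to the perfect-classification corner (0, 1) of the
unit ROC square; ties prefer higher specificity, then the lower threshold.
The Youden index (maximising sens + spec - 1) is available as an alternative,
never the default.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import UndefinedCurveError

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RocResult:
    thresholds: tuple[float, ...]       # descending
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float | None = None
    auc_ci95: tuple[float, float] | None = None
    auc_se: float | None = None
    cutoff: float | None = None
    cutoff_sensitivity: float | None = None
    cutoff_specificity: float | None = None

    def as_arrays(self):
        return (np.asarray(self.thresholds), np.asarray(self.sensitivity),
                np.asarray(self.specificity))


def _check_classes(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedCurveError(
            f"ROC needs both classes (got {pos.size} positives, {neg.size} negatives)"
        )
    return pos, neg


def roc_curve(scores, labels) -> RocResult:
    """Operating points over the data-driven threshold grid.

    Thresholds run from above the maximum score (sens 0, spec 1) down to
    below the minimum (sens 1, spec 0), visiting the midpoint between every
    pair of consecutive distinct score values.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(scores) | np.isnan(labels))
    scores, labels = scores[keep], labels[keep]
    pos, neg = _check_classes(scores, labels)

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate([[uniq[-1] + 1.0], mids[::-1], [uniq[0] - 1.0]])

    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    return RocResult(
        thresholds=tuple(float(t) for t in thresholds),
        sensitivity=tuple(float(s) for s in sens),
        specificity=tuple(float(s) for s in spec),
    )


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values: for each positive, the fraction of negatives
    it beats (ties half), and symmetrically for each negative."""
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size
    pos_sorted = np.sort(pos)
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / pos.size
    return v10, v01


def auc_with_ci(curve: RocResult, scores, labels, method: str = "delong") -> RocResult:
    """Fill the AUC fields of a computed curve.

    AUC is the trapezoidal integral of the curve (identical to the
    tie-adjusted Mann–Whitney statistic); the 95 % CI uses the DeLong
    variance estimator by default, or Hanley–McNeil with
    ``method="hanley-mcneil"``.  Bounds are clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(scores) | np.isnan(labels))
    scores, labels = scores[keep], labels[keep]
    pos, neg = _check_classes(scores, labels)

    _, sens, spec = curve.as_arrays()
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))

    if method == "delong":
        v10, v01 = _placements(pos, neg)
        var = 0.0
        if pos.size > 1:
            var += np.var(v10, ddof=1) / pos.size
        if neg.size > 1:
            var += np.var(v01, ddof=1) / neg.size
        se = float(np.sqrt(var))
    elif method == "hanley-mcneil":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc ** 2 / (1.0 + auc)
        m, n = pos.size, neg.size
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc ** 2) + (n - 1) * (q2 - auc ** 2)) / (m * n)
        se = float(np.sqrt(max(var, 0.0)))
    else:
        raise ValueError(f"unknown CI method {method!r}")

    lo = max(0.0, auc - _Z975 * se)
    hi = min(1.0, auc + _Z975 * se)
    return replace(curve, auc=auc, auc_ci95=(lo, hi), auc_se=se)


def optimal_cutoff_min_ss(curve: RocResult) -> RocResult:
    """Cut-off by the minimal sum of squared coordinates.

    Minimises (1 - sens)^2 + (1 - spec)^2 over the evaluated thresholds;
    ties prefer higher specificity, then the lower threshold.
    """
    thr, sens, spec = curve.as_arrays()
    obj = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    best = min(range(len(thr)), key=lambda i: (obj[i], -spec[i], thr[i]))
    return replace(
        curve,
        cutoff=float(thr[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
    )


def youden_cutoff(curve: RocResult) -> RocResult:
    """Alternative cut-off maximising Youden's J = sens + spec - 1."""
    thr, sens, spec = curve.as_arrays()
    j = sens + spec - 1.0
    best = min(range(len(thr)), key=lambda i: (-j[i], -spec[i], thr[i]))
    return replace(
        curve,
        cutoff=float(thr[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
    )


def analyze_scores(scores, labels, ci_method: str = "delong") -> RocResult:
    """Curve + AUC/CI + minimal-sum-of-squares cut-off in one call."""
    curve = roc_curve(scores, labels)
    curve = auc_with_ci(curve, scores, labels, method=ci_method)
    return optimal_cutoff_min_ss(curve)
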