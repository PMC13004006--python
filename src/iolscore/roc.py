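"""Nonparametric ROC analysis.

The empirical AUC is the Mann–Whitney estimator with half-credit for tied
positive–negative pairs, identical to the trapezoidal area under the
empirical ROC curve.  Standard errors are available in two flavours: the
Hanley–McNeil (1982) closed form, which depends only on the AUC and the
class counts, and the DeLong (1988) structural-components estimator
computed from the raw scores.  Coordinate tables follow the convention of
classical statistics packages: the smallest cutoff is min(observed) − 1,
the largest is max(observed) + 1, and interior cutoffs are midpoints of
consecutive distinct observed values; a subject is test-positive when its
score is >= the cutoff (higher score predicts vaginal delivery).

Two scores measured on the same subjects are compared with DeLong's paired
z test on the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError, ValidationError

__all__ = [
    "ROCPoint",
    "ROCCurve",
    "PairedAUCComparison",
    "empirical_auc",
    "auc_se",
    "auc_ci",
    "coordinate_table",
    "roc_curve",
    "compare_paired_auc",
]


@dataclass(frozen=True)
class ROCPoint:
    """One cutoff of the ROC coordinate table."""

    cutoff: float
    sensitivity: float
    one_minus_specificity: float

    def __post_init__(self):
        for name in ("sensitivity", "one_minus_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with AUC point and interval estimates."""

    points: tuple[ROCPoint, ...]
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int
    p_vs_half: float = field(default=float("nan"))

    def __post_init__(self):
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValidationError(
                f"AUC {self.auc} outside its CI ({self.ci_low}, {self.ci_high})")
        if min(self.n_positive, self.n_negative) < 1:
            raise DegenerateDataError("both outcome classes must be present")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_pos": self.n_positive, "n_neg": self.n_negative,
            "p_vs_half": self.p_vs_half,
        }


@dataclass(frozen=True)
class PairedAUCComparison:
    """DeLong paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    delta: float
    se_delta: float
    z: float
    p_value: float


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.ndim != 1:
        raise ValidationError("scores and labels must be one-dimensional")
    if scores.shape[0] != labels.shape[0]:
        raise ValidationError(
            f"scores ({scores.shape[0]}) and labels ({labels.shape[0]}) "
            "must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must all be finite")
    labels = labels.astype(float)
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValidationError("labels must be binary (0/1)")
    labels = labels.astype(bool)
    if labels.all() or not labels.any():
        raise DegenerateDataError(
            "need at least one positive and one negative label")
    return scores, labels


def empirical_auc(scores, labels) -> float:
    """Mann–Whitney AUC with half-credit ties.

    Equals the probability that a random positive outranks a random
    negative, counting exact ties as 1/2, and the trapezoidal area under
    the empirical ROC curve.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_placements(scores, labels):
    """Per-subject placement values V10 (positives) and V01 (negatives).

    V10_i = fraction of negatives strictly below positive i plus half the
    ties; V01_j symmetric.  Computed with midranks in O(n log n).
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)
    rank_pos_within = stats.rankdata(pos)
    rank_neg_within = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos_within) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg_within) / m
    return v10, v01


def auc_se(auc: float, n_pos: int, n_neg: int, method: str = "hanley_mcneil",
           scores=None, labels=None) -> float:
    """Standard error of an empirical AUC.

    ``hanley_mcneil`` uses the 1982 closed form with Q1 = A/(2−A) and
    Q2 = 2A²/(1+A).  ``delong`` requires ``scores`` and ``labels`` and
    uses the structural-components variance.
    """
    if min(int(n_pos), int(n_neg)) < 1:
        raise DegenerateDataError("n_pos and n_neg must both be >= 1")
    if method == "hanley_mcneil":
        if not 0.0 <= auc <= 1.0:
            raise ValidationError(f"auc must lie in [0, 1], got {auc}")
        a = float(auc)
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (a * (1.0 - a)
               + (n_pos - 1) * (q1 - a * a)
               + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
        return float(np.sqrt(max(var, 0.0)))
    if method == "delong":
        if scores is None or labels is None:
            raise ConfigurationError(
                "method='delong' requires the raw scores and labels")
        scores, labels = _validate_scores_labels(scores, labels)
        v10, v01 = _delong_placements(scores, labels)
        m, n = v10.size, v01.size
        # ddof=1 sample variances; a single positive (negative) contributes 0
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        return float(np.sqrt(s10 / m + s01 / n))
    raise ConfigurationError(
        f"unknown SE method {method!r}; choose 'hanley_mcneil' or 'delong'")


def auc_ci(auc: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic normal CI, auc ± z·se, truncated to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must lie in (0, 1), got {level}")
    if se < 0:
        raise ValidationError(f"se must be non-negative, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(lo), float(hi)


def coordinate_table(scores, labels) -> tuple[ROCPoint, ...]:
    """Cutoff coordinates in the classical statistics-package dialect.

    Cutoffs are min(observed) − 1, midpoints of consecutive distinct
    observed values, and max(observed) + 1, in ascending order.
    Test-positive means score >= cutoff.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    distinct = np.unique(scores)
    cutoffs = np.concatenate([
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 1.0],
    ])
    pos = scores[labels]
    neg = scores[~labels]
    points = []
    for c in cutoffs:
        sens = float((pos >= c).mean())
        fpr = float((neg >= c).mean())
        points.append(ROCPoint(cutoff=float(c), sensitivity=sens,
                               one_minus_specificity=fpr))
    return tuple(points)


def roc_curve(scores, labels, level: float = 0.95,
              se_method: str = "delong") -> ROCCurve:
    """Full ROC analysis: coordinate table, AUC, SE, CI and p vs 0.5.

    The null AUC = 0.5 is tested with the two-sided z statistic
    (AUC − 0.5)/SE.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    auc = empirical_auc(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    se = auc_se(auc, n_pos, n_neg, method=se_method,
                scores=scores, labels=labels)
    lo, hi = auc_ci(auc, se, level)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return ROCCurve(points=coordinate_table(scores, labels),
                    auc=auc, se=se, ci_low=lo, ci_high=hi,
                    n_positive=n_pos, n_negative=n_neg, p_vs_half=p)


def compare_paired_auc(scores_a, scores_b, labels) -> PairedAUCComparison:
    """DeLong paired z test on the difference of two AUCs.

    Both score vectors must be measured on the same subjects (same label
    vector).  Returns the difference ``auc_b − auc_a`` with its DeLong
    standard error and a two-sided p value.
    """
    scores_a, labels_a = _validate_scores_labels(scores_a, labels)
    scores_b, labels_b = _validate_scores_labels(scores_b, labels)
    v10_a, v01_a = _delong_placements(scores_a, labels_a)
    v10_b, v01_b = _delong_placements(scores_b, labels_b)
    m, n = v10_a.size, v01_a.size
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    delta = auc_b - auc_a
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var_delta = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                 + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    se_delta = float(np.sqrt(max(var_delta, 0.0)))
    if se_delta > 0:
        z = delta / se_delta
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z = 0.0
        p = 1.0 if delta == 0 else 0.0
    return PairedAUCComparison(auc_a=auc_a, auc_b=auc_b, delta=float(delta),
                               se_delta=se_delta, z=float(z), p_value=p)
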