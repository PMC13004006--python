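"""Binary-outcome logistic regression and stratified ROC summaries.

The age-adjusted odds-ratio analysis fits

    logit P(vaginal delivery) = b0 + b1 * composite_score + b2 * age

by maximum likelihood (iteratively reweighted least squares), with Wald
standard errors from the inverse observed information and OR confidence
intervals exp(coef ± z·SE).  Perfect separation is diagnosed explicitly
rather than returning divergent coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, SeparationError, ValidationError
from .roc import ROCCurve, roc_curve

__all__ = ["LogisticFit", "fit_logistic", "stratified_analysis"]

logger = logging.getLogger(__name__)

# |coefficient| beyond this on the logit scale is treated as evidence of
# (quasi-)separation: odds ratios above e^30 have no clinical meaning.
_SEPARATION_COEF_BOUND = 30.0


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``coefficients`` are on the log-odds scale; ``odds_ratios`` and their
    CI bounds are exponentiated.  Term order follows the design matrix
    columns.
    """

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float

    def summary_records(self) -> list[dict]:
        """Per-term records for JSON emission."""
        return [
            {"term": t,
             "coefficient": float(c), "se": float(s), "or": float(orr),
             "ci_low": float(lo), "ci_high": float(hi), "p": float(p)}
            for t, c, s, orr, lo, hi, p in zip(
                self.terms, self.coefficients, self.standard_errors,
                self.odds_ratios, self.ci_low, self.ci_high, self.p_values)
        ]


def _log_likelihood(y, eta):
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design, outcome, terms=None, max_iter: int = 100,
                 tol: float = 1e-8, level: float = 0.95) -> LogisticFit:
    """Fit a logistic regression by IRLS.

    Parameters
    ----------
    design : array-like, shape (n, p)
        Predictor matrix including the intercept column.
    outcome : array-like of 0/1, shape (n,)
    terms : sequence of str, optional
        Column names; defaults to ``x0`` (intercept), ``x1``, ...
    max_iter, tol
        IRLS stops when the largest coefficient change is below ``tol``.
    level
        Confidence level for the Wald odds-ratio intervals.

    Raises
    ------
    SeparationError
        When coefficients diverge (perfect or quasi-perfect separation).
    ValidationError
        For rank-deficient designs or invalid outcome coding.
    DegenerateDataError
        When the outcome has a single class.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.ndim != 2:
        raise ValidationError("design must be a 2-D matrix (include the intercept)")
    if y.ndim != 1 or y.shape[0] != x.shape[0]:
        raise ValidationError("outcome length must match the design rows")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("outcome must be binary (0/1)")
    if y.min() == y.max():
        raise DegenerateDataError("outcome has a single class; cannot fit")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    n, p = x.shape
    if terms is None:
        terms = tuple(f"x{j}" for j in range(p))
    else:
        terms = tuple(terms)
        if len(terms) != p:
            raise ValidationError("terms must name every design column")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix singular during IRLS; data are separated "
                "or the design is numerically degenerate") from None
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > _SEPARATION_COEF_BOUND:
            raise SeparationError(
                "coefficients diverged (|beta| > "
                f"{_SEPARATION_COEF_BOUND:g}); the outcome is perfectly or "
                "quasi-perfectly separated by the predictors")
        if step < tol:
            converged = True
            break

    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (x.T * w) @ x
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    ci_low = np.exp(beta - zq * se)
    ci_high = np.exp(beta + zq * se)
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return LogisticFit(
        terms=terms, coefficients=beta, standard_errors=se,
        odds_ratios=np.exp(beta), ci_low=ci_low, ci_high=ci_high,
        p_values=pvals, converged=converged, n_iterations=it,
        log_likelihood=_log_likelihood(y, eta))


def stratified_analysis(scores, labels, strata, level: float = 0.95,
                        se_method: str = "delong",
                        ) -> tuple[dict[object, ROCCurve], dict[object, str]]:
    """Per-stratum ROC curves (e.g., nulliparous vs multiparous).

    Returns ``(curves, skipped)``: one :class:`ROCCurve` per stratum that
    contains both outcome classes, and a reason string for every stratum
    that had to be skipped (empty, or single outcome class).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    if not (scores.shape == labels.shape == strata.shape):
        raise ValidationError("scores, labels and strata must have equal length")
    curves: dict[object, ROCCurve] = {}
    skipped: dict[object, str] = {}
    for value in np.unique(strata):
        mask = strata == value
        sub_labels = np.asarray(labels[mask], dtype=float)
        if mask.sum() == 0:
            skipped[value] = "empty stratum"
        elif sub_labels.min() == sub_labels.max():
            outcome = "positive" if sub_labels[0] == 1 else "negative"
            skipped[value] = f"single outcome class (all {outcome})"
        else:
            curves[value] = roc_curve(scores[mask], sub_labels,
                                      level=level, se_method=se_method)
    for value, reason in skipped.items():
        logger.warning("stratum %r skipped: %s", value, reason)
    return curves, skipped
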