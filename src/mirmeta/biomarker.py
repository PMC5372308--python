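"""Diagnostic-marker evaluation.

Empirical ROC/AUC (Mann-Whitney tie convention), an OLS risk score over
a marker panel — score = intercept + sum_j coef_j * E_j with E_j the log2
expression of marker j — Pearson correlation with its t-transform
p-value, and two small laboratory quantification formulas: relative qPCR
expression 2^-ddCt and the caliper xenograft volume L * W^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class RiskScoreModel:
    marker_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    fitted_scores: np.ndarray
    auc: float

    def score(self, expression: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new samples (columns = marker_ids)."""
        X = expression[self.marker_ids].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients

    def equation(self, ndigits: int = 3) -> str:
        """Human-readable `risk score = c1*E_m1 + ... + intercept` string."""
        terms = []
        for m, c in zip(self.marker_ids, self.coefficients):
            sign = "+" if c >= 0 else "-"
            terms.append(f"{sign} {abs(c):.{ndigits}f}*E_{m}")
        sign0 = "+" if self.intercept >= 0 else "-"
        body = " ".join(terms).lstrip("+ ")
        return f"risk score = {body} {sign0} {abs(self.intercept):.{ndigits}f}"


def roc_auc(scores, labels, case_label=None) -> RocCurve:
    """Empirical ROC curve and AUC.

    AUC is P(score_case > score_control) + 0.5 * P(tie) over all
    case-control pairs (the Mann-Whitney statistic); the curve is the
    empirical threshold sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if case_label is None:
        case_label = classes[-1]
    y = (labels == case_label).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("one class is absent")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    # Mann-Whitney AUC via midranks: exact, ties counted half
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc))


def fit_linear_risk_score(
    expression: pd.DataFrame, labels, case_label=None
) -> RiskScoreModel:
    """OLS of a 0/1 class indicator on a log2 marker panel, with intercept.

    The fitted linear predictor is the risk score; its in-sample AUC is
    attached.  A singular design is rejected naming the collinear
    markers.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    if case_label is None:
        case_label = classes[-1]
    y = (labels == case_label).astype(float)
    markers = list(expression.columns)
    X = expression.to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need more samples than markers + 1")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # name the offending markers via pivoted QR on the design
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True)
        dropped = sorted(markers[i - 1] for i in piv[rank:] if i > 0)
        raise ValueError(f"singular design matrix; collinear markers: {dropped}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    scores = design @ beta
    return RiskScoreModel(
        marker_ids=markers,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        fitted_scores=scores,
        auc=roc_auc(scores, labels, case_label).auc,
    )


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Pearson r, r^2 and the two-sided p from the t transform
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r * r), float(p)


def ddct_relative_expression(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method."""
    cts = [ct_target_sample, ct_reference_sample, ct_target_calibrator,
           ct_reference_calibrator]
    if not np.all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_reference_sample) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return float(2.0 ** (-ddct))


def tumor_volume(length: float, width: float) -> float:
    """Caliper xenograft volume (mm^3): length * width^2 / 2."""
    if length <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    if width > length:
        warnings.warn("width exceeds length; computing anyway", stacklevel=2)
    return float(length * width * width / 2.0)
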