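"""Classification metrics, DeLong ROC machinery, dependent-correlation
comparison, and the two reference baselines (LASSO-logistic, SVM).

The AUC is the Mann-Whitney two-sample statistic with ties counted 1/2; its
variance and the covariance between two correlated AUCs use DeLong's
structural-components estimator, giving normal-approximation confidence
intervals and the paired z test for comparing ROC curves on the same
subjects. Spearman correlations of two predictors with a shared criterion
are compared with Steiger's z for overlapping dependent correlations on
Fisher-transformed rank correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, spearmanr
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n: int
    n_pos: int
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "threshold": self.threshold,
            "n": self.n,
            "n_pos": self.n_pos,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
        }


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p: float


@dataclass
class CorrelationComparison:
    rho_pred: float
    rho_alt: float
    rho_inter: float
    z: float
    p_two_sided: float
    p_one_sided: float
    n: int


def confusion_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Sensitivity, specificity, accuracy at a decision threshold (>= rule).

    A class absent from the labels leaves the corresponding rate NaN rather
    than silently 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sens = float(np.mean(pred[pos])) if pos.any() else float("nan")
    spec = float(np.mean(~pred[neg])) if neg.any() else float("nan")
    acc = float(np.mean(pred == (labels == 1)))
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        threshold=threshold,
        n=len(labels),
        n_pos=int(pos.sum()),
    )


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be present for ROC analysis")
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def auc_delong(scores, labels):
    """(AUC, DeLong variance, 95% CI clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v10, v01, auc = _structural_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), float(var), ci


def delong_paired_test(scores_a, scores_b, labels) -> AucComparison:
    """Covariance-aware z test for two correlated AUCs on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("score lists and labels must cover the same subjects")
    v10a, v01a, auc_a = _structural_components(scores_a, labels)
    v10b, v01b, auc_b = _structural_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    var = 0.0
    if m > 1:
        cov10 = np.cov(v10a, v10b, ddof=1)
        var += (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m
    if n > 1:
        cov01 = np.cov(v01a, v01b, ddof=1)
        var += (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0.0:
        z = 0.0
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return AucComparison(
        auc_a=float(auc_a), auc_b=float(auc_b), difference=float(diff),
        variance=float(var), z=float(z), p=float(p),
    )


def dependent_correlation_test(pred, alt, criterion) -> CorrelationComparison:
    """Steiger's z comparing two overlapping dependent Spearman correlations.

    Tests whether rho(pred, criterion) differs from rho(alt, criterion),
    accounting for the correlation between the two predictors. Rows with a
    missing criterion (or predictor) value are dropped listwise.
    """
    df = pd.DataFrame({"pred": pred, "alt": alt, "crit": criterion}).dropna()
    n = len(df)
    if n < 10:
        raise ValueError("need at least 10 complete triples")
    for col in df.columns:
        if df[col].nunique() < 2:
            raise ValueError(f"column {col!r} is constant")
    r12 = float(spearmanr(df["pred"], df["crit"]).statistic)
    r13 = float(spearmanr(df["alt"], df["crit"]).statistic)
    r23 = float(spearmanr(df["pred"], df["alt"]).statistic)
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rm2 = 0.5 * (r12 * r12 + r13 * r13)
    f = min((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0) if rm2 < 1.0 else 1.0
    h = (1.0 - f * rm2) / (1.0 - rm2) if rm2 < 1.0 else 1.0
    denom = 2.0 * (1.0 - r23) * h
    if denom <= 0.0:
        z = 0.0
    else:
        z = (z12 - z13) * math.sqrt((n - 3) / denom)
    p_two = 2.0 * norm.sf(abs(z))
    p_one = norm.sf(z)
    return CorrelationComparison(
        rho_pred=r12, rho_alt=r13, rho_inter=r23, z=float(z),
        p_two_sided=float(min(p_two, 1.0)), p_one_sided=float(p_one), n=n,
    )


def baseline_fit(
    X_train,
    y_train,
    X_test,
    kind: str,
    seed: int = 0,
    C: float | None = None,
) -> np.ndarray:
    """Reference baselines on the flattened one-hot node features.

    ``lasso-logistic``: L1-penalized logistic regression; the penalty is
    chosen by stratified cross-validation on the training data unless ``C``
    is given. ``max-margin``: an RBF-kernel SVM whose signed decision values
    are mapped through the logistic link so scores are monotone in margin.
    Returns probability-scale scores for the test rows.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training data")
    if kind == "lasso-logistic":
        if C is not None:
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=C, random_state=seed, max_iter=2000
            )
        else:
            clf = LogisticRegressionCV(
                penalty="l1",
                solver="liblinear",
                use_legacy_attributes=False,
                Cs=np.logspace(-2, 2, 8),
                cv=StratifiedKFold(3, shuffle=True, random_state=seed),
                random_state=seed,
                max_iter=2000,
            )
        clf.fit(X_train, y_train)
        return clf.predict_proba(X_test)[:, 1]
    if kind == "max-margin":
        clf = SVC(kernel="rbf", gamma="scale", random_state=seed)
        clf.fit(X_train, y_train)
        return expit(clf.decision_function(X_test))
    raise ValueError("kind must be 'lasso-logistic' or 'max-margin'")
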