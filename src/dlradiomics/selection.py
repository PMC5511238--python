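"""Feature selection and linear-SVM phenotype prediction.

Two selection steps precede the classifier, exactly as in the pipeline's
design: an unpaired two-sample Student's t-test (pooled variance) keeps
features with p below alpha, and the F-score — the ratio of between-class
to within-class scatter of a single feature — ranks the survivors, of
which the top m enter a linear support-vector machine (box constraint C).
Evaluation is leave-one-out cross-validation or a single time-based
split; selection is re-done inside every fold so the held-out case never
influences it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "SelectionReport",
    "PredictionReport",
    "ttest_filter",
    "fscore_rank",
    "select_top",
    "loocv_predict",
    "time_split_predict",
    "roc_auc",
    "confusion_metrics",
]


@dataclass
class SelectionReport:
    kept: np.ndarray  # indices surviving the t-test
    p_values: np.ndarray  # per-feature p (NaN where undefined)
    f_scores: np.ndarray  # per-feature F-score (NaN where not computed)
    top: np.ndarray  # final top-m indices


@dataclass
class PredictionReport:
    """Held-out decision scores, predictions and the full metric panel."""

    scores: np.ndarray
    predicted: np.ndarray
    labels: np.ndarray
    auc: float
    acc: float
    sens: float
    spec: float
    ppv: float
    npv: float
    mcc: float
    roc_points: np.ndarray  # (n_thresholds, 2) of (FPR, TPR)
    case_ids: list | None = None

    def metrics(self) -> dict:
        return {
            "AUC": self.auc,
            "ACC": self.acc,
            "SENS": self.sens,
            "SPEC": self.spec,
            "PPV": self.ppv,
            "NPV": self.npv,
            "MCC": self.mcc,
        }


def _check_two_class(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not np.array_equal(u, [0, 1]):
        raise ValueError(f"need both classes 0 and 1, got labels {u}")


def ttest_filter(features: np.ndarray, labels: np.ndarray, alpha: float = 0.05):
    """Keep features whose two-sample pooled-variance t-test has p < alpha.

    Returns (kept_indices, p_values).  Features with zero pooled variance
    have no defined t statistic; they get p = NaN, are never kept, and
    trigger a warning.  No multiple-testing correction is applied — the
    significance criterion is the plain per-feature p < alpha.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    _check_two_class(y)
    a, b = X[y == 1], X[y == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 cases per class for the t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
        p = np.asarray(res.pvalue, dtype=np.float64)
    pooled_ss = ((a - a.mean(0)) ** 2).sum(0) + ((b - b.mean(0)) ** 2).sum(0)
    undefined = pooled_ss == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} features with zero pooled variance excluded",
            stacklevel=2,
        )
        p[undefined] = np.nan
    kept = np.flatnonzero(np.nan_to_num(p, nan=np.inf) < alpha)
    return kept, p


def fscore_rank(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature F-score: between-class over within-class scatter.

    F(i) = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / [s⁺² + s⁻²] with sample variances per
    class.  A zero denominator scores +inf when the numerator is positive
    (perfectly compact, separated classes) and 0 otherwise.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    _check_two_class(y)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 cases per class for the F-score")
    grand = X.mean(axis=0)
    num = (pos.mean(0) - grand) ** 2 + (neg.mean(0) - grand) ** 2
    den = pos.var(0, ddof=1) + neg.var(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    f[(den == 0) & (num > 0)] = np.inf
    f[(den == 0) & (num == 0)] = 0.0
    return f


def select_top(fscores: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest F-scores; ties break toward lower index."""
    if m < 1:
        raise ValueError("m must be >= 1")
    f = np.asarray(fscores, dtype=np.float64)
    if m > f.size:
        warnings.warn(f"m={m} exceeds {f.size} features; taking all", stacklevel=2)
        m = f.size
    # stable sort on -f keeps lower indices first among ties
    order = np.argsort(-f, kind="stable")
    return np.sort(order[:m])


def _fit_and_score(X_tr, y_tr, X_te, alpha, m, svm_c):
    """One fold: standardize, t-test filter, F-score top-m, linear SVM."""
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs, Xt = (X_tr - mu) / sd, (X_te - mu) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, _ = ttest_filter(Xs, y_tr, alpha)
    if kept.size == 0:
        # nothing significant: fall back to ranking all well-defined features
        kept = np.arange(Xs.shape[1])
    f = fscore_rank(Xs[:, kept], y_tr)
    top = kept[select_top(np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max), min(m, kept.size))]
    clf = SVC(kernel="linear", C=svm_c)
    clf.fit(Xs[:, top], y_tr)
    return clf.decision_function(Xt[:, top])


def _report(scores, labels, case_ids=None) -> PredictionReport:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    predicted = (scores > 0).astype(int)
    auc, points = roc_auc(scores, labels)
    acc, sens, spec, ppv, npv, mcc = confusion_metrics(predicted, labels)
    return PredictionReport(
        scores=scores,
        predicted=predicted,
        labels=labels,
        auc=auc,
        acc=acc,
        sens=sens,
        spec=spec,
        ppv=ppv,
        npv=npv,
        mcc=mcc,
        roc_points=points,
        case_ids=case_ids,
    )


def loocv_predict(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    m: int = 100,
    svm_c: float = 1.0,
    case_ids=None,
) -> PredictionReport:
    """Leave-one-out cross-validated prediction with in-fold selection.

    For each case the t-test filter, F-score ranking and SVM are fitted
    on all other cases only, so no information about the held-out case
    leaks into selection or the classifier.  Metrics are computed from
    the n held-out decision scores.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 cases")
    _check_two_class(y)
    scores = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y[tr]).size < 2:
            raise ValueError(f"fold {i}: training set is single-class")
        scores[i] = _fit_and_score(X[tr], y[tr], X[i : i + 1], alpha, m, svm_c)[0]
    return _report(scores, y, case_ids)


def time_split_predict(
    features: np.ndarray,
    labels: np.ndarray,
    diagnosis_time: np.ndarray,
    cutoff: float,
    alpha: float = 0.05,
    m: int = 100,
    svm_c: float = 1.0,
    case_ids=None,
) -> PredictionReport:
    """Single chronological split: train on cases diagnosed before the
    cutoff, evaluate once on the later cases."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    t = np.asarray(diagnosis_time)
    early, late = t < cutoff, t >= cutoff
    if not early.any() or not late.any():
        raise ValueError("cutoff leaves an empty train or test side")
    if np.unique(y[early]).size < 2:
        raise ValueError("training side is single-class")
    scores = _fit_and_score(X[early], y[early], X[late], alpha, m, svm_c)
    ids = [case_ids[i] for i in np.flatnonzero(late)] if case_ids is not None else None
    return _report(scores, y[late], ids)


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """AUC as the Mann-Whitney rank statistic with half-credit for ties,
    plus the ROC curve points (FPR, TPR) at every distinct threshold."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    _check_two_class(y)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    ranks = stats.rankdata(s)  # average ranks give tie half-credit
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    distinct = np.r_[np.flatnonzero(np.diff(ss)), ss.size - 1]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return float(auc), points


def confusion_metrics(predicted: np.ndarray, labels: np.ndarray):
    """(ACC, SENS, SPEC, PPV, NPV, MCC) from binary predictions.

    Positive class is 1 (mutation-like).  Any undefined ratio (empty
    predicted class, or a zero factor under the MCC root) returns 0 with
    a warning instead of NaN.
    """
    p = np.asarray(predicted)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("length mismatch between predictions and labels")
    if not (np.isin(p, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("predictions and labels must be binary")
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    n = tp + tn + fp + fn

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning 0", stacklevel=3)
            return 0.0
        return num / den

    acc = (tp + tn) / n
    sens = _ratio(tp, tp + fn, "SENS")
    spec = _ratio(tn, tn + fp, "SPEC")
    ppv = _ratio(tp, tp + fp, "PPV")
    npv = _ratio(tn, tn + fn, "NPV")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("MCC undefined (zero denominator factor); returning 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom2)
    return acc, sens, spec, ppv, npv, float(mcc)
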