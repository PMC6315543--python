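"""Classification of samples on a class-associated PC loading.

Linear discriminant analysis is fitted on the selected loading(s) with
empirical class priors and evaluated by resubstitution, matching the way
small-n microarray discriminant analyses are usually reported. The 2x2
confusion table (rows = true class, control first; columns = predicted) is
summarized by sensitivity, precision, F1 and accuracy for the case class,
by ROC-AUC via the Mann-Whitney identity, and by Fisher's exact test with
the conditional maximum-likelihood odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .containers import CASE, CONTROL
from .pca import DegenerateInputError

__all__ = [
    "ClassificationReport",
    "lda_fit_predict",
    "confusion_metrics",
    "roc_auc",
    "fisher_exact_2x2",
    "evaluate_classification",
]


@dataclass
class ClassificationReport:
    """Discriminant scores, predictions and the full metric suite."""

    discriminant_score: pd.Series
    predicted: pd.Series
    confusion: np.ndarray  # rows: true (control, case); cols: predicted
    sensitivity: float
    precision: float
    f1: float
    accuracy: float
    auc: float
    odds_ratio: float
    fisher_p: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["discriminant_score"] = self.discriminant_score.to_dict()
        d["predicted"] = self.predicted.to_dict()
        d["confusion"] = self.confusion.tolist()
        return d

    def confusion_frame(self) -> pd.DataFrame:
        idx = pd.Index([CONTROL, CASE], name="true")
        cols = pd.Index([CONTROL, CASE], name="predicted")
        return pd.DataFrame(self.confusion, index=idx, columns=cols)


def _check_two_classes(labels: pd.Series) -> np.ndarray:
    classes = set(labels.unique())
    if classes != {CONTROL, CASE}:
        raise DegenerateInputError(
            f"labels must contain both {CONTROL!r} and {CASE!r}, got {sorted(classes)}"
        )
    return (labels == CASE).to_numpy()


def lda_fit_predict(
    loading: "pd.Series | pd.DataFrame",
    labels: pd.Series,
    priors: str = "empirical",
    cv_folds: int | None = None,
) -> tuple[pd.Series, pd.Series, np.ndarray]:
    """Fit LDA on loading value(s) and predict the samples.

    By default predictions are resubstitution (fit and predict on the same
    samples); pass ``cv_folds`` for stratified cross-validated predictions
    instead. Returns (discriminant scores, predictions, confusion table)
    with confusion rows = true class (control first), columns = predicted.
    """
    X = loading.to_frame() if isinstance(loading, pd.Series) else loading
    labels = labels.reindex(X.index)
    _check_two_classes(labels)
    arr = X.to_numpy(dtype=float)
    if np.all(arr.std(axis=0) == 0):
        raise DegenerateInputError("loading is constant across samples")
    y = labels.to_numpy()
    prior_arg = None if priors == "empirical" else np.array([0.5, 0.5])
    lda = LinearDiscriminantAnalysis(priors=prior_arg)
    if cv_folds:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=False)
        pred = cross_val_predict(lda, arr, y, cv=skf)
        lda.fit(arr, y)
    else:
        lda.fit(arr, y)
        pred = lda.predict(arr)
    # signed distance to the decision boundary, positive toward "case"
    raw = lda.decision_function(arr)
    if lda.classes_[1] != CASE:
        raw = -raw
    scores = pd.Series(raw, index=X.index, name="discriminant_score")
    predicted = pd.Series(pred, index=X.index, name="predicted")
    confusion = _confusion_table(labels, predicted)
    return scores, predicted, confusion


def _confusion_table(true: pd.Series, predicted: pd.Series) -> np.ndarray:
    order = [CONTROL, CASE]
    table = np.zeros((2, 2), dtype=int)
    for i, t in enumerate(order):
        for j, p in enumerate(order):
            table[i, j] = int(((true == t) & (predicted == p)).sum())
    return table


def confusion_metrics(
    confusion: "np.ndarray | list[list[int]]", positive: int = 1
) -> tuple[float, float, float, float]:
    """(sensitivity, precision, F1, accuracy) for the positive class.

    ``positive`` is the row/column index of the positive class (1 = the
    case/disease class in this package's convention). Metrics whose
    denominator is zero are reported as NaN (undefined), never as 0.
    """
    table = np.asarray(confusion, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("confusion must be a non-negative 2x2 table")
    if table.sum() == 0:
        raise ValueError("confusion table is empty")
    if positive not in (0, 1):
        raise ValueError("positive must be 0 or 1")
    neg = 1 - positive
    tp = table[positive, positive]
    fn = table[positive, neg]
    fp = table[neg, positive]
    tn = table[neg, neg]

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    sensitivity = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    if math.isnan(sensitivity) or math.isnan(precision) or sensitivity + precision == 0:
        f1 = math.nan if (math.isnan(sensitivity) or math.isnan(precision)) else 0.0
    else:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    accuracy = (tp + tn) / table.sum()
    return sensitivity, precision, f1, accuracy


def roc_auc(scores: pd.Series, labels: pd.Series, positive: str = CASE) -> float:
    """ROC-AUC by the Mann-Whitney identity (ties count 1/2).

    Scores are taken as increasing with the positive class.
    """
    labels = labels.reindex(scores.index)
    y = (labels == positive).to_numpy()
    if y.all() or not y.any():
        raise DegenerateInputError("both classes must be present for AUC")
    return float(roc_auc_score(y, scores.to_numpy(dtype=float)))


def fisher_exact_2x2(
    confusion: "np.ndarray | list[list[int]]",
) -> tuple[float, float]:
    """Two-sided Fisher exact p and conditional-MLE odds ratio.

    The odds ratio is the conditional maximum-likelihood estimate under the
    noncentral hypergeometric model with both margins fixed — shrunk
    relative to the sample cross-product ratio ``ad/bc``. A zero cell gives
    0 or +inf depending on the side.
    """
    table = np.asarray(confusion, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    or_cmle = float(_odds_ratio(table, kind="conditional").statistic)
    return p, or_cmle


def evaluate_classification(
    loading: pd.Series,
    labels: pd.Series,
    priors: str = "empirical",
    cv_folds: int | None = None,
) -> ClassificationReport:
    """Run LDA on a loading and compute the full metric suite.

    AUC is computed on the loading itself (signed so that the case class
    has the larger mean) rather than the LDA posterior; in one dimension
    the two are monotone equivalents.
    """
    labels = labels.reindex(loading.index)
    scores, predicted, confusion = lda_fit_predict(loading, labels, priors, cv_folds)
    sens, prec, f1, acc = confusion_metrics(confusion, positive=1)
    signed = loading.astype(float)
    case_mask = _check_two_classes(labels)
    if signed.to_numpy()[case_mask].mean() < signed.to_numpy()[~case_mask].mean():
        signed = -signed
    auc = roc_auc(signed, labels)
    fisher_p, or_cmle = fisher_exact_2x2(confusion)
    return ClassificationReport(
        discriminant_score=scores,
        predicted=predicted,
        confusion=confusion,
        sensitivity=sens,
        precision=prec,
        f1=f1,
        accuracy=acc,
        auc=auc,
        odds_ratio=or_cmle,
        fisher_p=fisher_p,
    )
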