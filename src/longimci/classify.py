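"""RBF-SVM leave-one-out evaluation with per-fold feature selection.

Each subject is held out once; F-score ranking, optional z-scoring, and
the SVM fit all use the remaining n−1 subjects only, so no information
from the held-out subject leaks into selection or training.  The pooled
held-out decision values yield one ROC curve and one AUC per run.

The kernel is the Gaussian RBF K(x1, x2) = exp(−‖x1−x2‖² / (2σ²)); the
width may be given as σ or as γ = 1/(2σ²).  Progressive MCI is the
positive class throughout: sensitivity is the converter detection rate
and specificity the stable-MCI detection rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FeatureMatrix
from .select import f_score, select_top_k
from .types import POSITIVE_LABEL

__all__ = [
    "SvmConfig",
    "CVResult",
    "rbf_kernel",
    "confusion_metrics",
    "roc_auc",
    "loo_evaluate",
    "sweep_feature_count",
    "permutation_baseline",
]


@dataclass
class SvmConfig:
    """RBF-SVM hyperparameters.

    ``sigma`` (kernel width σ) takes precedence over ``gamma``; when
    neither is given γ defaults to 1/n_features.  ``scale`` toggles the
    per-fold z-scoring of features before the kernel.  C defaults to 1
    (the common library default); no inner tuning loop is run.
    """

    C: float = 1.0
    sigma: float | None = None
    gamma: float | None = None
    scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def resolve_gamma(self, n_features: int) -> float:
        if self.sigma is not None:
            return 1.0 / (2.0 * self.sigma**2)
        if self.gamma is not None:
            return self.gamma
        return 1.0 / n_features


@dataclass
class CVResult:
    """Pooled leave-one-out predictions and summary metrics.

    ``table`` holds one row per subject (fold id, decision score,
    predicted and true label).  ACC/SEN/SPE are percentages; AUC is on
    [0, 1]; ``roc`` is the (FPR, TPR) point list of the pooled curve.
    Metrics are kept at full precision; rounding happens only in
    :meth:`summary`.
    """

    table: pd.DataFrame
    acc: float
    sen: float
    spe: float
    auc: float
    roc: np.ndarray
    k_used: int

    def summary(self) -> dict:
        return {
            "ACC": round(self.acc, 2),
            "SEN": round(self.sen, 2),
            "SPE": round(self.spe, 2),
            "AUC": round(self.auc, 4),
            "k": self.k_used,
        }


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(−‖x1−x2‖² / (2σ²)); 1 iff x1 == x2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("feature vectors must have equal length")
    sq = float(np.sum((x1 - x2) ** 2))
    return float(np.exp(-sq / (2.0 * sigma**2)))


def confusion_metrics(
    predictions: np.ndarray, labels: np.ndarray, positive=POSITIVE_LABEL
) -> tuple[float, float, float]:
    """(ACC, SEN, SPE) in percent from aligned predictions and labels.

    Raises if either class is absent from ``labels`` (sensitivity or
    specificity would be undefined).
    """
    pred = np.asarray(predictions)
    true = np.asarray(labels)
    if pred.shape != true.shape:
        raise ValueError("predictions and labels must align")
    pos = true == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present to compute SEN/SPE")
    tp = int(np.sum((pred == positive) & pos))
    tn = int(np.sum((pred != positive) & ~pos))
    fp = int(np.sum((pred == positive) & ~pos))
    fn = int(np.sum((pred != positive) & pos))
    acc = 100.0 * (tp + tn) / true.size
    sen = 100.0 * tp / (tp + fn)
    spe = 100.0 * tn / (tn + fp)
    return acc, sen, spe


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, positive=POSITIVE_LABEL
) -> tuple[float, np.ndarray]:
    """ROC curve and AUC from real-valued decision scores.

    The curve sweeps every distinct score as threshold (ties grouped);
    AUC is the trapezoidal area, which equals the Mann-Whitney
    concordance probability with ties counted one half.  Constant scores
    yield AUC 0.5 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if np.all(s == s[0]):
        warnings.warn("constant decision scores; AUC is 0.5 by convention")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def _as_xy(features, labels=None):
    if isinstance(features, FeatureMatrix):
        X = features.data.to_numpy(dtype=float)
        y = features.labels.to_numpy() if labels is None else np.asarray(labels)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels)
    if y is None or len(y) != X.shape[0]:
        raise ValueError("labels must align with feature rows")
    return X, y


def loo_evaluate(
    features, labels=None, k: int | None = None,
    svm: SvmConfig | None = None, positive=POSITIVE_LABEL,
) -> CVResult:
    """Leave-one-out evaluation with per-fold selection and scaling.

    For each subject the F-score ranking, top-``k`` selection, z-scoring
    parameters and SVM are fit on the other n−1 subjects; the held-out
    subject receives a decision score and predicted label.  Summary
    metrics pool all n held-out predictions.  ``k`` defaults to all
    features.

    Raises if any training fold would lose a class (fewer than 2
    subjects per class overall).
    """
    X, y = _as_xy(features, labels)
    svm = svm or SvmConfig()
    n, p = X.shape
    k = p if k is None else int(k)
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, {p}]")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("a leave-one-out training fold would lose a class")

    y_bin = (y == positive).astype(int)
    scores = np.empty(n)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        fs = f_score(X[tr], y[tr], positive)
        idx = select_top_k(fs, k)
        Xtr, Xte = X[tr][:, idx], X[i:i + 1, idx]
        if svm.scale:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = SVC(C=svm.C, kernel="rbf", gamma=svm.resolve_gamma(k),
                  random_state=svm.seed)
        clf.fit(Xtr, y_bin[tr])
        scores[i] = float(clf.decision_function(Xte)[0])
        pred_bin = int(clf.predict(Xte)[0])
        preds[i] = positive if pred_bin == 1 else classes[classes != positive][0]

    acc, sen, spe = confusion_metrics(preds, y, positive)
    auc, roc = roc_auc(scores, y, positive)
    table = pd.DataFrame({
        "fold": np.arange(n),
        "score": scores,
        "predicted": preds,
        "true": y,
    })
    return CVResult(table=table, acc=acc, sen=sen, spe=spe, auc=auc,
                    roc=roc, k_used=k)


def sweep_feature_count(
    features, labels=None, k_range=None,
    svm: SvmConfig | None = None, positive=POSITIVE_LABEL,
) -> tuple[pd.DataFrame, int]:
    """Leave-one-out metrics as a function of the selected feature count.

    Returns the per-k metric table and the accuracy-argmax k (smallest k
    on ties).  The argmax uses the pooled held-out accuracy itself — an
    optimistic model-selection convention; for a leakage-safe choice,
    nest the sweep inside an outer validation split.
    """
    X, y = _as_xy(features, labels)
    if k_range is None:
        k_range = range(1, X.shape[1] + 1)
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("k_range is empty")
    rows = []
    for k in ks:
        res = loo_evaluate(X, y, k=k, svm=svm, positive=positive)
        rows.append({"k": k, "ACC": res.acc, "SEN": res.sen,
                     "SPE": res.spe, "AUC": res.auc})
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["ACC"].idxmax(), "k"]  # idxmax takes first max
    return curve, int(best)


def permutation_baseline(
    features, labels=None, k: int | None = None,
    svm: SvmConfig | None = None, n_permutations: int = 20,
    seed: int = 0, positive=POSITIVE_LABEL,
) -> pd.DataFrame:
    """Leave-one-out accuracies under random label permutations.

    A chance-level control: with labels shuffled, accuracy should match
    the null expectation sum_c P(pred = c) P(y = c), which the returned
    frame reports per permutation (column ``chance``, in percent,
    computed from that run's own prediction frequencies) alongside
    ``acc``.  For a classifier that always voted with the majority the
    chance rate would equal the majority-class rate; a balanced voter
    sits near 50%.
    """
    X, y = _as_xy(features, labels)
    rng = np.random.default_rng(seed)
    n = len(y)
    class_freq = {c: np.mean(y == c) for c in np.unique(y)}
    rows = []
    for r in range(n_permutations):
        yp = rng.permutation(y)
        res = loo_evaluate(X, yp, k=k, svm=svm, positive=positive)
        pred = res.table["predicted"].to_numpy()
        chance = 100.0 * sum(
            np.mean(pred == c) * class_freq[c] for c in class_freq
        )
        rows.append({"acc": res.acc, "chance": chance})
    return pd.DataFrame(rows)
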