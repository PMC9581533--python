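"""Evaluation protocol for the macrophage classifier.

The headline metrics come from repeated random 50/50 train/test splits
(10,000 by default): for each repeat a tree is fitted on the training
half and one-vs-rest sensitivity and specificity are computed per class
from the test-half confusion matrix; means and standard deviations are
reported over repeats.  Shuffled k-fold cross-validation (k=5), ROC
curves from leaf class proportions, and two-sample Kolmogorov-Smirnov
distribution comparisons complete the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .tree_classifier import TreeHyperparams, fit_tree, predict, predict_scores


def confusion_matrix(y_true, y_pred, labels) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted."""
    labels = np.asarray(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def confusion_metrics(cm: np.ndarray) -> Dict[str, np.ndarray]:
    """One-vs-rest sensitivity, specificity, PPV and NPV per class.

    Undefined rates (zero denominator) are NaN, never 0.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp

    def rate(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
    }


@dataclass
class EvalReport:
    """Summary of a repeated-split evaluation."""

    labels: np.ndarray
    sensitivity_mean: np.ndarray
    sensitivity_sd: np.ndarray
    specificity_mean: np.ndarray
    specificity_sd: np.ndarray
    n_repeats: int
    n_redraws: int
    confusion_pooled: np.ndarray
    cv_scores: Optional[np.ndarray] = None
    roc_curves: dict = field(default_factory=dict)

    @property
    def cv_mean(self) -> Optional[float]:
        return None if self.cv_scores is None else float(np.mean(self.cv_scores))

    def to_dict(self) -> dict:
        d = {
            "labels": self.labels.tolist(),
            "sensitivity_mean": self.sensitivity_mean.tolist(),
            "sensitivity_sd": self.sensitivity_sd.tolist(),
            "specificity_mean": self.specificity_mean.tolist(),
            "specificity_sd": self.specificity_sd.tolist(),
            "n_repeats": self.n_repeats,
            "n_redraws": self.n_redraws,
            "confusion_pooled": self.confusion_pooled.tolist(),
        }
        if self.cv_scores is not None:
            d["cv_scores"] = self.cv_scores.tolist()
            d["cv_mean"] = self.cv_mean
        if self.roc_curves:
            d["roc_curves"] = {
                str(k): {"fpr": v[0].tolist(), "tpr": v[1].tolist(),
                         "auc": float(v[3])}
                for k, v in self.roc_curves.items()
            }
        return d


def repeated_split_eval(X, y, hp: Optional[TreeHyperparams] = None,
                        n_repeats: int = 10000, seed=0,
                        test_fraction: float = 0.5) -> EvalReport:
    """Repeated random train/test split evaluation.

    Each repeat draws a uniform random 50/50 split (no stratification),
    fits the tree on the training half and scores the test half.  A repeat
    whose training or test half misses a class entirely is redrawn and the
    redraw counted.  Per-class one-vs-rest sensitivity and specificity are
    averaged over repeats; the confusion matrices are also pooled.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    labels = np.unique(y)
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    hp = hp or TreeHyperparams()
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round((1.0 - test_fraction) * n))
    sens = np.empty((n_repeats, len(labels)))
    spec = np.empty((n_repeats, len(labels)))
    pooled = np.zeros((len(labels), len(labels)), dtype=np.int64)
    n_redraws = 0
    for rep in range(n_repeats):
        while True:
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if (len(np.unique(y[tr])) == len(labels)
                    and len(np.unique(y[te])) == len(labels)):
                break
            n_redraws += 1
        model = fit_tree(X[tr], y[tr], hp)
        pred = predict(model, X[te])
        cm = confusion_matrix(y[te], pred, labels)
        pooled += cm
        m = confusion_metrics(cm)
        sens[rep] = m["sensitivity"]
        spec[rep] = m["specificity"]
    return EvalReport(
        labels=labels,
        sensitivity_mean=np.nanmean(sens, axis=0),
        sensitivity_sd=np.nanstd(sens, axis=0),
        specificity_mean=np.nanmean(spec, axis=0),
        specificity_sd=np.nanstd(spec, axis=0),
        n_repeats=n_repeats, n_redraws=n_redraws, confusion_pooled=pooled,
    )


def roc_curve(scores, labels, positive_class) -> Tuple[np.ndarray, np.ndarray,
                                                       np.ndarray, float]:
    """ROC by threshold sweep over distinct scores; trapezoidal AUC.

    ``scores`` are the positive-class scores (e.g. the leaf proportion of
    the positive class from :func:`predict_scores`).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_class
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep the last index of each distinct score (threshold boundaries)
    distinct = np.r_[ss[1:] != ss[:-1], True]
    tps, fps, thr = tps[distinct], fps[distinct], ss[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, thr]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def tree_roc(X, y, positive_class, hp: Optional[TreeHyperparams] = None,
             seed=0, test_fraction: float = 0.5):
    """ROC of one random split, scoring with leaf class proportions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    hp = hp or TreeHyperparams()
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round((1.0 - test_fraction) * n))
    while True:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if (len(np.unique(y[tr])) == len(labels)
                and len(np.unique(y[te])) == len(labels)):
            break
    model = fit_tree(X[tr], y[tr], hp)
    col = int(np.nonzero(model.classes_ == positive_class)[0][0])
    scores = predict_scores(model, X[te])[:, col]
    return roc_curve(scores, y[te], positive_class)


def kfold_cv(X, y, hp: Optional[TreeHyperparams] = None, k: int = 5,
             seed=0) -> Tuple[np.ndarray, float]:
    """Shuffled k-fold cross-validation; per-fold accuracy and its mean."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k samples")
    hp = hp or TreeHyperparams()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    scores = []
    for i in range(k):
        te = folds[i]
        tr = np.concatenate([folds[j] for j in range(k) if j != i])
        model = fit_tree(X[tr], y[tr], hp)
        scores.append(float(np.mean(predict(model, X[te]) == y[te])))
    scores = np.asarray(scores)
    return scores, float(scores.mean())


def ks_compare(sample_a, sample_b, alpha: float = 0.05):
    """Two-sample Kolmogorov-Smirnov test with a rejection flag at alpha."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)
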