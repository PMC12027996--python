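"""Score-based evaluation: logistic scoring, ROC, AUC and Youden's J.

The positive class is rivalry throughout.  Sensitivity = TP/(TP+FN),
Specificity = TN/(TN+FP) and J = Sensitivity + Specificity - 1; the ROC
curve is traced over thresholds at every distinct score (plus sentinels)
and AUC is computed by the trapezoidal rule over (FPR, TPR) — which equals
the Mann-Whitney pair-ranking probability with ties counted one half.

Scores come from an unpenalized maximum-likelihood binary logistic
regression over a selected indicator subset; perfect separation falls back
to a large-but-finite coefficient fit (flagged).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

#: coefficient magnitude treated as numerically separated
_SEPARATION_CAP = 40.0


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return np.nan if self.tp + self.fn == 0 else \
            self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return np.nan if self.tn + self.fp == 0 else \
            self.tn / (self.tn + self.fp)


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    j: np.ndarray
    auc: float
    optimal_threshold: float
    flags: list[str] = field(default_factory=list)

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity

    @property
    def max_j(self) -> float:
        return float(np.max(self.j))


def youden_j(sensitivity: float, specificity: float) -> float:
    """J = Sensitivity + Specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.dtype.kind in "US":
        y = (labels == "rivalry").astype(int)
    else:
        y = np.asarray(labels, dtype=float)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("labels must be binary (rivalry = 1)")
        y = y.astype(int)
    return scores, y


def confusion_at(scores, labels, threshold: float,
                 ) -> tuple[ConfusionCounts, tuple[float, float]]:
    """Confusion counts at ``score >= threshold => predicted rivalry``."""
    scores, y = _validate_scores_labels(scores, labels)
    pred = scores >= threshold
    counts = ConfusionCounts(tp=int(np.sum(pred & (y == 1))),
                             fp=int(np.sum(pred & (y == 0))),
                             tn=int(np.sum(~pred & (y == 0))),
                             fn=int(np.sum(~pred & (y == 1))))
    return counts, (counts.sensitivity, counts.specificity)


def auc_mann_whitney(scores, labels) -> float:
    """Pair-ranking AUC: P(rivalry score > fusion score) + 0.5 P(tie)."""
    scores, y = _validate_scores_labels(scores, labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_curve(scores, labels) -> RocResult:
    """Full ROC sweep with per-threshold J and trapezoidal AUC.

    Thresholds are all distinct scores plus -inf/+inf sentinels; the
    optimal threshold maximizes J (ties broken toward the lower
    threshold).
    """
    scores, y = _validate_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        sens[i] = np.sum(pred & (y == 1)) / n_pos
        spec[i] = np.sum(~pred & (y == 0)) / n_neg
    j = sens + spec - 1.0
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))   # tied-FPR vertices by ascending TPR
    auc = float(np.trapezoid(sens[order], fpr[order]))
    best = np.flatnonzero(j >= j.max() - 1e-12)
    optimal = float(thresholds[best].min())
    return RocResult(thresholds, sens, spec, j, auc, optimal)


def optimal_threshold_scan(scores, labels) -> float:
    """Exhaustive max-J scan over midpoints between adjacent sorted scores
    (plus outer sentinels); independent check of the ROC sweep."""
    scores, y = _validate_scores_labels(scores, labels)
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], uniq,
                            (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1
                            else [], [np.inf]])
    best_j, best_thr = -np.inf, np.nan
    for thr in np.sort(cands):
        _, (se, sp) = confusion_at(scores, y, thr)
        jv = se + sp - 1.0
        if jv > best_j + 1e-12:
            best_j, best_thr = jv, thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# Logistic scoring

class LogisticRivalryScorer(BaseEstimator):
    """Unpenalized ML binary logistic score for rivalry (positive class).

    Fits by Newton iterations (log-likelihood tolerance 1e-8, at most 100
    iterations).  Under perfect separation the unpenalized MLE diverges;
    the fit then falls back to coefficients capped at a large finite
    magnitude and sets ``separation_``.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    separation_ : bool
    """

    def __init__(self, cap: float = _SEPARATION_CAP, max_iter: int = 100):
        self.cap = cap
        self.max_iter = max_iter

    def fit(self, X, y) -> "LogisticRivalryScorer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(y) == 1 \
                and len(np.asarray(y)) == X.shape[1]:
            X = X.T
        _, y01 = _validate_scores_labels(np.zeros(X.shape[0]), y)
        if min(y01.sum(), len(y01) - y01.sum()) < 2:
            raise ValueError("need at least 2 cases per class")
        if np.any(np.ptp(X, axis=0) == 0):
            raise ValueError("constant predictor")
        # standardize internally for numerical stability; coefficients are
        # reported on the original scale
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xs = (X - mu) / sd
        design = sm.add_constant(Xs, has_constant="add")
        self.separation_ = False
        params = None
        separated = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y01, design).fit(method="newton",
                                                maxiter=self.max_iter,
                                                tol=1e-8, disp=0)
                params = np.asarray(res.params, dtype=float)
            except Exception:
                params = None
            separated = any("PerfectSeparation" in w.category.__name__
                            for w in caught)
        if separated or params is None or not np.all(np.isfinite(params)) \
                or np.max(np.abs(params[1:])) > self.cap:
            # perfect (or quasi-) separation: cap the standardized fit
            from sklearn.linear_model import LogisticRegression
            lr = LogisticRegression(C=1e4, max_iter=1000).fit(Xs, y01)
            params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
            params = np.clip(params, -self.cap, self.cap)
            self.separation_ = True
        coef_std = params[1:]
        self.coef_ = coef_std / sd
        self.intercept_ = float(params[0] - np.sum(coef_std * mu / sd))
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            X = X.T
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return np.column_stack([1.0 - p, p])

    def score_samples(self, X) -> np.ndarray:
        """Fitted probability of rivalry (the ROC score)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.score_samples(X) >= threshold).astype(int)

    def evaluate(self, X, y) -> RocResult:
        """Resubstitution-style ROC of the fitted score on (X, y)."""
        result = roc_curve(self.score_samples(X), y)
        if self.separation_:
            result.flags.append("perfect separation; capped coefficients")
        return result


def fit_logistic_score(X, y, **kwargs) -> LogisticRivalryScorer:
    """Functional wrapper over :class:`LogisticRivalryScorer`."""
    return LogisticRivalryScorer(**kwargs).fit(X, y)


def kfold_roc(X, y, k: int = 5, seed: int = 0) -> RocResult:
    """Optional k-fold cross-validated ROC (clearly labelled alternative to
    the default resubstitution ROC)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, y01 = _validate_scores_labels(np.zeros(X.shape[0]), y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y01))
    folds = np.array_split(order, k)
    scores = np.empty(len(y01))
    for fold in folds:
        train = np.setdiff1d(order, fold)
        est = LogisticRivalryScorer().fit(X[train], y01[train])
        scores[fold] = est.score_samples(X[fold])
    result = roc_curve(scores, y01)
    result.flags.append(f"{k}-fold cross-validated scores")
    return result


# ---------------------------------------------------------------------------
# Output

def write_roc(result: RocResult, tsv_path: str | Path | None = None,
              json_path: str | Path | None = None) -> None:
    if tsv_path is not None:
        pd.DataFrame({"threshold": result.thresholds, "fpr": result.fpr,
                      "tpr": result.tpr, "j": result.j}
                     ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        idx = int(np.argmax(result.j))
        Path(json_path).write_text(json.dumps({
            "auc": result.auc,
            "optimal_threshold": result.optimal_threshold,
            "sensitivity": float(result.sensitivity[idx]),
            "specificity": float(result.specificity[idx]),
            "youden_j": float(result.j[idx]),
            "flags": result.flags}, indent=1))


def plot_roc(result: RocResult, path: str | Path) -> None:
    """Save a ROC plot (optional; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    order = np.argsort(result.fpr)
    ax.plot(result.fpr[order], result.tpr[order], lw=1.5,
            label=f"AUC = {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
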