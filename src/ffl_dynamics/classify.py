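"""Gaussian Naive Bayes biomarker classification with LOOCV and ROC/AUC.

Small gene panels (e.g. a two-gene diagnostic signature) are evaluated by a
Gaussian Naive Bayes classifier: class priors are sample frequencies and each
feature gets an independent per-class normal density.  Performance is the area
under the ROC curve of the positive-class posterior, estimated by
leave-one-out cross-validation on the training cohort and, when an independent
test cohort is supplied, by training on the full training set and scoring the
test samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class FeaturePanel:
    """Samples x features matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be 2-D with one row per label")
        if not np.isfinite(self.X).all():
            raise ValueError("panel contains missing/non-finite values")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class NBModel:
    """Class priors and per-class per-feature Gaussian parameters."""

    priors: np.ndarray  # shape (2,)
    means: np.ndarray  # shape (2, n_features)
    variances: np.ndarray  # shape (2, n_features), floored at eps
    eps: float

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lj = np.empty((X.shape[0], 2))
        for c in (0, 1):
            resid = (X - self.means[c]) ** 2 / self.variances[c]
            lj[:, c] = np.log(self.priors[c]) - 0.5 * (
                resid + np.log(2.0 * np.pi * self.variances[c])
            ).sum(axis=1)
        return lj

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """p(class=1 | x), computed in log space."""
        lj = self.log_joint(X)
        m = lj.max(axis=1, keepdims=True)
        w = np.exp(lj - m)
        return w[:, 1] / w.sum(axis=1)


def fit_nb(panel: FeaturePanel, eps: float | None = None) -> NBModel:
    """Fit Gaussian class-conditionals; variance floor eps avoids degeneracy.

    Default eps is 1e-9 times the largest overall feature variance (falling
    back to 1e-12 when the panel is globally constant).
    """
    classes = np.unique(panel.y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit the classifier")
    if eps is None:
        gvar = float(np.var(panel.X, axis=0).max())
        eps = 1e-9 * gvar if gvar > 0 else 1e-12
    priors = np.array([(panel.y == c).mean() for c in (0, 1)])
    means = np.vstack([panel.X[panel.y == c].mean(axis=0) for c in (0, 1)])
    variances = np.vstack([panel.X[panel.y == c].var(axis=0) for c in (0, 1)])
    variances = np.maximum(variances, eps)
    return NBModel(priors, means, variances, eps)


def loocv_scores(panel: FeaturePanel) -> np.ndarray:
    """Posterior p(class=1) for each sample under leave-one-out cross-validation.

    Deterministic; a fold whose training data loses an entire class is scored
    with the prior-only model (a warning is logged).
    """
    if panel.n < 4:
        raise ValueError("need n >= 4 samples for LOOCV")
    # fixed eps across folds so fold models are comparable
    gvar = float(np.var(panel.X, axis=0).max())
    eps = 1e-9 * gvar if gvar > 0 else 1e-12
    scores = np.empty(panel.n)
    for i in range(panel.n):
        mask = np.ones(panel.n, dtype=bool)
        mask[i] = False
        y_tr = panel.y[mask]
        if len(np.unique(y_tr)) < 2:
            logger.warning("fold %d lost an entire class; scoring with prior only", i)
            scores[i] = y_tr.mean()
            continue
        sub = FeaturePanel(panel.X[mask], y_tr, panel.feature_names, [panel.sample_ids[j] for j in range(panel.n) if mask[j]])
        scores[i] = fit_nb(sub, eps=eps).posterior(panel.X[i : i + 1])[0]
    return scores


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC sweep and AUC by the rank (Mann-Whitney) formulation, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)

    # threshold sweep from high to low score, collapsing tied scores
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.where(np.diff(sorted_scores))[0], len(scores) - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return ROCResult(thresholds, fpr, tpr, float(auc))


def make_panel(expr, genes: list[str], task: str = "diagnosis") -> FeaturePanel:
    """Build a FeaturePanel from an expression matrix and a label task.

    ``diagnosis`` labels case samples 1 and controls 0; ``recurrence`` keeps
    only samples with a recurrence annotation (yes -> 1, no -> 0).
    """
    missing = [g for g in genes if g not in expr.features]
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {missing}")
    ann = expr.samples
    if task == "diagnosis":
        ids = list(ann.index)
        y = (ann["group"] == "case").astype(int).to_numpy()
    elif task == "recurrence":
        keep = ann["recurrence"].isin(["yes", "no"])
        ids = list(ann.index[keep])
        y = (ann.loc[keep, "recurrence"] == "yes").astype(int).to_numpy()
    else:
        raise ValueError("task must be 'diagnosis' or 'recurrence'")
    X = expr.values.loc[genes, ids].to_numpy(dtype=float).T
    return FeaturePanel(X, y, list(genes), ids)


def evaluate_panel(genes: list[str], train, test=None, task: str = "diagnosis") -> dict:
    """LOOCV AUC of the gene panel (and each single gene) on the training cohort.

    When ``test`` is given the model is refit on the full training cohort and
    the AUC on the independent test cohort is reported as well.
    """
    report: dict = {"genes": list(genes), "task": task}
    panel = make_panel(train, genes, task)
    report["train_loocv_auc"] = roc_auc(loocv_scores(panel), panel.y).auc
    report["single_gene_train_auc"] = {}
    for g in genes:
        sp = make_panel(train, [g], task)
        report["single_gene_train_auc"][g] = roc_auc(loocv_scores(sp), sp.y).auc
    if test is not None:
        model = fit_nb(panel)
        tp = make_panel(test, genes, task)
        report["test_auc"] = roc_auc(model.posterior(tp.X), tp.y).auc
        report["single_gene_test_auc"] = {}
        for g in genes:
            smodel = fit_nb(make_panel(train, [g], task))
            stp = make_panel(test, [g], task)
            report["single_gene_test_auc"][g] = roc_auc(smodel.posterior(stp.X), stp.y).auc
    return report
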