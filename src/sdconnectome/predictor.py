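"""RBF-SVM classifiers under leave-one-out cross-validation.

The classifier is a support vector machine with the radial basis kernel
K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2), gamma > 0. For every
leave-one-out fold, features come from that fold's own significance mask
(the held-out subject never influences feature selection), the penalty C and
kernel width gamma are grid-searched by stratified cross-validation on the
training subjects only, the winning pair is refit on all training subjects,
and the held-out subject is predicted. Decision values are pooled across
folds into a single ROC curve.

The patient (SD) group is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectome import AdjacencyMatrix
from .edge_stats import GROUP_SD, MaskFamily, _check_groups
from .features import FeatureSpec, materialize_features

__all__ = [
    "SvmConfig",
    "ConfusionMatrix",
    "ModelReport",
    "metrics_from_confusion",
    "roc_auc",
    "grid_search_svm",
    "loocv_evaluate",
]

logger = logging.getLogger(__name__)

# LIBSVM guide's exponential grids: C = 2^-5, 2^-3, ..., 2^15 and
# gamma = 2^-15, 2^-13, ..., 2^3.
_DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 17, 2))
_DEFAULT_GAMMA_GRID = tuple(float(2.0**k) for k in range(-15, 5, 2))


@dataclass(frozen=True)
class SvmConfig:
    """Grid-search and cross-validation settings for the RBF-SVM."""

    C_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA_GRID
    inner_cv_folds: int = 5
    seed: int = 0
    standardize: bool = False
    search: str = "nested"  # "nested": per-fold grid search; "global": one search on all data

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if min(self.C_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("C and gamma must be positive")
        if self.search not in ("nested", "global"):
            raise ValueError("search must be 'nested' or 'global'")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with SD as the positive class: tp/fn over SD, tn/fp over HC."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_hc(self) -> int:
        return self.tn + self.fp

    @property
    def n_sd(self) -> int:
        return self.fn + self.tp


def metrics_from_confusion(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity). Sensitivity is the detection rate
    among SD subjects, specificity among HC."""
    if cm.n_sd == 0 or cm.n_hc == 0:
        raise ValueError("both groups must be represented")
    total = cm.n_sd + cm.n_hc
    return (
        (cm.tp + cm.tn) / total,
        cm.tp / cm.n_sd,
        cm.tn / cm.n_hc,
    )


def roc_auc(decision_values, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and AUC from decision values.

    AUC equals the Mann–Whitney pairwise-comparison probability with ties
    given half credit.
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray([1 if g == GROUP_SD else 0 for g in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def grid_search_svm(X: np.ndarray, y: np.ndarray, cfg: SvmConfig) -> tuple[float, float, float]:
    """Pick (C, gamma) by stratified k-fold accuracy on (X, y).

    Grids are scanned in ascending order with a strict-improvement rule, so
    ties resolve to the smallest C, then the smallest gamma (the smoothest
    model) and the result is deterministic given ``cfg.seed``.
    """
    n_splits = min(cfg.inner_cv_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few subjects in a class for inner cross-validation")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
    best = (-np.inf, None, None)
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            score = cross_val_score(
                SVC(C=C, gamma=gamma, kernel="rbf"), X, y, cv=cv
            ).mean()
            if score > best[0]:
                best = (score, C, gamma)
    return best[1], best[2], best[0]


@dataclass
class ModelReport:
    """Leave-one-out evaluation of one connection-feature model."""

    model_name: str
    family: str
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: list[tuple[float, float]]
    auc: float
    chosen_params: list[tuple[float, float]]  # (C, gamma) per fold
    n_features: list[int] = field(default_factory=list)  # per fold
    decision_values: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "family": self.family,
            "confusion": {
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tp": self.confusion.tp,
            },
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_points": self.roc_points,
            "auc": self.auc,
            "chosen_params": self.chosen_params,
            "n_features": self.n_features,
        }


def _subset_edges(edges, X, edge_subset):
    if edge_subset is None:
        return X, edges
    keep = [k for k, e in enumerate(edges) if e in edge_subset]
    return X[:, keep], [edges[k] for k in keep]


def loocv_evaluate(
    spec: FeatureSpec,
    masks: MaskFamily,
    adjs: list[AdjacencyMatrix],
    groups,
    cfg: SvmConfig = SvmConfig(),
    edge_subset: set | None = None,
) -> ModelReport:
    """Leave-one-out evaluation of one feature spec with per-fold masks.

    For each subject s the features come from ``masks.fold_masks[s]`` (never
    the full mask); (C, gamma) is tuned by inner stratified CV on the
    training subjects. ``edge_subset``, when given, restricts the candidate
    edges (used by the connection-subsampling experiment). A fold whose
    feature set is empty predicts the training majority class.
    """
    groups = np.asarray(groups)
    _check_groups(groups)
    n_subj = len(adjs)
    if n_subj < 3:
        raise ValueError("cohort too small for leave-one-out")
    if masks.n_folds != n_subj:
        raise ValueError(
            f"mask family has {masks.n_folds} folds for {n_subj} subjects"
        )
    y = np.asarray([1 if g == GROUP_SD else 0 for g in groups])
    if y.min() == y.max():
        raise ValueError("both groups must be present")

    global_params: tuple[float, float] | None = None
    if cfg.search == "global":
        Xg, edges_g, _ = materialize_features(spec, masks.full_mask, adjs)
        Xg, _ = _subset_edges(edges_g, Xg, edge_subset)
        if Xg.shape[1] == 0:
            global_params = (sorted(cfg.C_grid)[0], sorted(cfg.gamma_grid)[0])
        else:
            C, gamma, _ = grid_search_svm(Xg, y, cfg)
            global_params = (C, gamma)

    preds = np.empty(n_subj, dtype=int)
    decisions = np.empty(n_subj, dtype=float)
    chosen: list[tuple[float, float]] = []
    n_feats: list[int] = []

    for s in range(n_subj):
        X, edges, _ = materialize_features(spec, masks.fold_masks[s], adjs)
        X, edges = _subset_edges(edges, X, edge_subset)
        train = np.ones(n_subj, dtype=bool)
        train[s] = False
        y_tr = y[train]
        if y_tr.min() == y_tr.max():
            raise ValueError("single-class training set in a fold")
        n_feats.append(X.shape[1])
        if X.shape[1] == 0:
            # no significant connections in this fold: majority-class fallback
            logger.info(
                "%s: empty feature set in fold %d; predicting training majority",
                spec.name, s,
            )
            maj = int(round(y_tr.mean()))
            preds[s] = maj
            decisions[s] = y_tr.mean() - 0.5
            chosen.append((np.nan, np.nan))
            continue
        X_tr, X_te = X[train], X[~train]
        if cfg.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        if global_params is not None:
            C, gamma = global_params
        else:
            C, gamma, _ = grid_search_svm(X_tr, y_tr, cfg)
        clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(X_tr, y_tr)
        preds[s] = int(clf.predict(X_te)[0])
        decisions[s] = float(clf.decision_function(X_te)[0])
        chosen.append((C, gamma))

    cm = ConfusionMatrix(
        tn=int(((preds == 0) & (y == 0)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
        tp=int(((preds == 1) & (y == 1)).sum()),
    )
    acc, sens, spec_ = metrics_from_confusion(cm)
    points, auc = roc_auc(decisions, groups)
    return ModelReport(
        model_name=spec.name,
        family=spec.family,
        confusion=cm,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec_,
        roc_points=points,
        auc=auc,
        chosen_params=chosen,
        n_features=n_feats,
        decision_values=decisions.tolist(),
    )
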