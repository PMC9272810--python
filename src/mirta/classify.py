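"""Predictive biomarker selection and classification between two clinical levels.

Mirrors the prognostic workflow for a binary clinical contrast (e.g. response
vs non-response, MSI-high vs MSS): features are ranked by presence in the
top-n across stratified cross-validation folds using several selectors
(AdaBoost with depth-1 trees, random-forest impurity importance, L1-penalized
logistic regression), then a chosen classifier (random forest, logistic
regression or linear SVM) is evaluated by stratified k-fold CV with
out-of-fold predictions pooled into one ROC curve, a confusion matrix at the
0.5 probability threshold, and a PCA projection of the samples on the
selected features.

Standardization is fitted on each training split only — test folds never leak
into the scaler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import AnalysisError, ValidationError
from .survival import FeatureRanking

logger = logging.getLogger(__name__)

SELECTION_METHODS = ("adaboost", "random_forest", "l1_logistic")
CLASSIFIERS = ("random_forest", "logistic_regression", "svm")


def _check_labels(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise AnalysisError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < k:
        raise AnalysisError(
            f"smallest class has {counts.min()} samples; need >= k={k}")


def _selector_importance(method: str, X: np.ndarray, y: np.ndarray,
                         seed: int) -> np.ndarray:
    if method == "adaboost":
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=100, random_state=seed)
        est.fit(X, y)
        return est.feature_importances_
    if method == "random_forest":
        est = RandomForestClassifier(n_estimators=200, random_state=seed)
        est.fit(X, y)
        return est.feature_importances_
    if method == "l1_logistic":
        scaler = StandardScaler().fit(X)
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                 random_state=seed)
        est.fit(scaler.transform(X), y)
        return np.abs(est.coef_[0])
    raise ValidationError(f"unknown selection method {method!r}")


def select_predictive(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    methods: Sequence[str] = SELECTION_METHODS,
    k: int = 5,
    top_n: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by presence in the CV top candidates for a binary contrast.

    ``X`` is samples x features; ``labels`` binary (0/1). Stratified folds;
    per (fold, method) the ``top_n`` features by importance are counted.
    Deterministic under ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    for m in methods:
        if m not in SELECTION_METHODS:
            raise ValidationError(f"unknown selection method {m!r}")
    y = np.asarray(labels)
    _check_labels(y, k)
    if X.shape[1] < top_n:
        raise AnalysisError(f"need >= top_n={top_n} features, got {X.shape[1]}")
    feat_ids = list(X.columns)
    X_arr = X.to_numpy()

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    counts = {m: pd.Series(0.0, index=feat_ids) for m in methods}
    importance_sum = pd.Series(0.0, index=feat_ids)
    n_combos = 0
    for fold_i, (train, _) in enumerate(skf.split(X_arr, y)):
        for method in methods:
            imp = _selector_importance(method, X_arr[train], y[train], seed + fold_i)
            top_idx = np.argsort(-imp, kind="stable")[:top_n]
            for j in top_idx:
                counts[method].iloc[j] += 1
            if imp.max() > 0:
                importance_sum += imp / imp.max()
            n_combos += 1

    presence = sum(counts.values()) / n_combos
    table = pd.DataFrame({
        "feature_id": feat_ids,
        "presence": presence.to_numpy(),
        "mean_importance": (importance_sum / n_combos).to_numpy(),
    })
    for m in methods:
        table[f"presence_{m}"] = (counts[m] / k).to_numpy()
    table = table.sort_values(["presence", "mean_importance", "feature_id"],
                              ascending=[False, False, True]).reset_index(drop=True)
    return FeatureRanking(table=table, k=k, models=tuple(methods), top_n=top_n)


# ---------------------------------------------------------------------------
# Classification with cross-validated performance


@dataclass
class ClassifierReport:
    """Cross-validated classification performance on selected features."""

    model: str
    selected_features: list[str]
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    roc: pd.DataFrame = field(repr=False)  # pooled out-of-fold fpr/tpr/threshold
    pooled_auc: float = float("nan")
    confusion: np.ndarray = field(repr=False, default=None)  # at 0.5 threshold
    pca_coordinates: pd.DataFrame = field(repr=False, default=None)
    pca_explained_variance: tuple[float, float] = (float("nan"), float("nan"))


def _make_classifier(model: str, seed: int):
    if model == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if model == "logistic_regression":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000, random_state=seed))
    if model == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="linear", probability=True,
                                 random_state=seed))
    raise ValidationError(f"unknown classifier {model!r}")


def train_and_cv(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    selected_features: Sequence[str] | None = None,
    model: str = "random_forest",
    k: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold evaluation of a classifier on selected features.

    Out-of-fold predicted probabilities are pooled for the ROC curve and the
    confusion matrix (0.5 threshold); per-fold AUCs give mean +/- sd. Any
    standardization lives inside the per-fold pipeline, so test folds never
    inform the scaler. A PCA projection (2 components) of all samples on the
    selected features is attached for visualization.
    """
    y = np.asarray(labels)
    _check_labels(y, k)
    feats = list(selected_features) if selected_features is not None else list(X.columns)
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise AnalysisError(f"selected features absent from matrix: {missing[:5]}")
    Xs = X[feats]
    if len(Xs) < k:
        raise AnalysisError(f"fewer samples ({len(Xs)}) than folds ({k})")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for train, test in skf.split(Xs.to_numpy(), y):
        clf = _make_classifier(model, seed)
        clf.fit(Xs.to_numpy()[train], y[train])
        proba = clf.predict_proba(Xs.to_numpy()[test])[:, 1]
        oof[test] = proba
        fold_aucs.append(float(roc_auc_score(y[test], proba)))

    fpr, tpr, thr = roc_curve(y, oof)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    coords, evr = pca_projection(Xs)
    return ClassifierReport(
        model=model,
        selected_features=feats,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        sd_auc=float(np.std(fold_aucs)),
        roc=roc,
        pooled_auc=float(auc(fpr, tpr)),
        confusion=confusion_matrix(y, (oof >= 0.5).astype(int)),
        pca_coordinates=coords,
        pca_explained_variance=evr,
    )


def pca_projection(X: pd.DataFrame) -> tuple[pd.DataFrame, tuple[float, float]]:
    """First two principal components of samples x selected features.

    Centered internally; deterministic sign convention: within each
    component, the loading with the largest magnitude is made positive.
    Returns per-sample coordinates (PC1, PC2) and the explained-variance
    ratios.
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise AnalysisError("PCA needs >= 3 samples and >= 2 features")
    arr = X.to_numpy(dtype=float)
    if (np.ptp(arr, axis=0) > 0).sum() < 2:
        raise AnalysisError("fewer than 2 non-degenerate (varying) dimensions")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(arr)
    for i in range(2):
        j = np.argmax(np.abs(pca.components_[i]))
        if pca.components_[i, j] < 0:
            pca.components_[i] *= -1
            coords[:, i] *= -1
    out = pd.DataFrame(coords, columns=["PC1", "PC2"], index=X.index)
    evr = pca.explained_variance_ratio_
    return out, (float(evr[0]), float(evr[1]))
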