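"""Multivariate oscillatory fingerprint: six per-subject electrophysiological
variables and the discrimination analyses built on them.

The six features are (1) HPC theta relative power in active wake, (2) entropy
of the mean theta coherence across REM/QWK/ACT, (3) PFC aperiodic exponent in
active wake, (4) PFC theta-high-gamma amplitude correlation in active wake,
(5) HPC-PFC theta coherence in REM (Fisher-z), and (6) the REM-ACT state-map
distance. Analyses: z-scored PCA (SVD), a regularized linear discriminant on
the leading PCs with leave-one-out cross-validation (z-scoring and PCA refit
inside each fold to avoid leakage), univariate logistic-regression AUCs, and
Ward hierarchical clustering with silhouette-selected cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, silhouette_score

FEATURE_NAMES = (
    "hpc_theta_rel_power_act",
    "theta_coherence_entropy",
    "pfc_exponent_act",
    "pfc_theta_gamma_r_act",
    "rem_theta_coherence_z",
    "rem_act_distance",
)


def extract_fingerprint(metrics: dict, subject: str = "",
                        group: str = "") -> pd.Series:
    """Assemble the six-feature vector from per-subject stage outputs."""
    missing = [k for k in FEATURE_NAMES
               if k not in metrics or metrics[k] is None
               or (isinstance(metrics[k], float) and np.isnan(metrics[k]))]
    if missing:
        raise ValueError(f"missing fingerprint elements: {missing}")
    s = pd.Series({k: float(metrics[k]) for k in FEATURE_NAMES})
    s["subject"] = subject or metrics.get("subject", "")
    s["group"] = group or metrics.get("group", "")
    return s


def cohort_frame(fingerprints: list[pd.Series]) -> pd.DataFrame:
    return pd.DataFrame(fingerprints).reset_index(drop=True)


@dataclass
class PCAResult:
    scores: np.ndarray           # (n_subjects, n_components)
    loadings: np.ndarray         # (n_features, n_components), orthonormal
    explained_variance_ratio: np.ndarray


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance feature column(s) at index {zero.tolist()}")
    return (X - X.mean(axis=0)) / sd


def pca_project(X: np.ndarray) -> PCAResult:
    """Z-scored PCA by SVD; explained-variance fractions sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 subjects")
    Z = _zscore_cols(X)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    var = s ** 2
    return PCAResult(scores=u * s, loadings=vt.T,
                     explained_variance_ratio=var / var.sum())


@dataclass
class LDAResult:
    train_accuracy: float
    loocv_accuracy: float
    coef: np.ndarray
    intercept: float


def _fit_zscore_pca_lda(X, y, n_pcs, shrinkage):
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_pcs, vt.shape[0])
    proj = vt[:k].T
    scores = Z @ proj
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(scores, y)

    def predict(Xnew):
        return lda.predict(((Xnew - mu) / sd) @ proj)

    return lda, predict, scores


def lda_classify(X: np.ndarray, groups: np.ndarray, n_pcs: int = 2,
                 shrinkage: float = 0.1) -> LDAResult:
    """Regularized LDA on the leading PCs, with leakage-free LOOCV.

    Each leave-one-out fold re-estimates the column z-scores and the PCA
    projection from its training subjects before refitting the discriminant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(groups).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("LDA expects exactly two groups")
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 subjects for LOOCV")
    lda, predict, scores = _fit_zscore_pca_lda(X, y, n_pcs, shrinkage)
    train_acc = float(np.mean(predict(X) == y))
    hits = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        _, predict_i, _ = _fit_zscore_pca_lda(X[mask], y[mask], n_pcs, shrinkage)
        hits += predict_i(X[i:i + 1])[0] == y[i]
    return LDAResult(train_accuracy=train_acc,
                     loocv_accuracy=float(hits / len(y)),
                     coef=lda.coef_[0].copy(),
                     intercept=float(lda.intercept_[0]))


def univariate_auc(feature: np.ndarray, groups: np.ndarray) -> float:
    """AUC of a single-feature logistic regression, oriented to >= 0.5."""
    x = np.asarray(feature, dtype=float).reshape(-1, 1)
    y = np.asarray(groups)
    classes = np.unique(y.astype(str))
    if len(classes) != 2:
        raise ValueError("need exactly two groups")
    yb = (y.astype(str) == classes[1]).astype(int)
    if np.ptp(x) == 0:
        warnings.warn("constant feature: AUC undefined, reporting 0.5")
        return 0.5
    clf = LogisticRegression()
    clf.fit(x, yb)
    auc = roc_auc_score(yb, clf.decision_function(x))
    return float(max(auc, 1.0 - auc))


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    leaf_order: np.ndarray
    labels: np.ndarray
    k: int
    silhouette: float


def hierarchical_cluster(X: np.ndarray, metric: str = "euclidean",
                         z_score: bool = True) -> ClusterResult:
    """Ward agglomeration with silhouette-selected cluster count.

    ``metric='euclidean'`` clusters subjects; ``metric='correlation'``
    clusters variables (rows of ``X`` are the items in both cases).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 items")
    if metric == "correlation" and np.any(X.std(axis=1) == 0):
        raise ValueError("zero-variance row with correlation metric")
    if z_score:
        X = _zscore_cols(X)
    d = pdist(X, metric=metric)
    Z = linkage(d, method="ward")
    best = (2, -np.inf, None)
    dmat = squareform(d)
    for k in range(2, n):
        labels = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(dmat, labels, metric="precomputed")
        if s > best[1] + 1e-12:
            best = (k, s, labels)
    k, s, labels = best
    return ClusterResult(linkage_matrix=Z, leaf_order=leaves_list(Z),
                         labels=labels, k=k, silhouette=float(s))
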