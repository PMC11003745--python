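"""REM vs ACT brain-state decoding from state-map coordinates or whole-spectrum
features, with bootstrap confidence intervals and repeated holdout AUCs.

One model is fitted per experimental group (pooling that group's epochs);
discrimination is summarized by the AUC-ROC. The state-map decoders use the
two map coordinates; the whole-spectrum decoder uses 1-55 Hz (0.5 Hz bins)
PFC power, HPC power, and coherence blocks, evaluated by 100 repeated
stratified 80/20 splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

MODELS = ("svm-linear", "svm-rbf", "random-forest")


@dataclass
class DecodingResult:
    model: str
    feature_set: str
    auc: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    holdout_mean: float = np.nan
    holdout_sd: float = np.nan
    n_epochs: int = 0


def _make_model(model: str, seed: int):
    if model == "svm-linear":
        return make_pipeline(StandardScaler(), LinearSVC(C=1.0))
    if model == "svm-rbf":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0,
                                                   gamma="scale"))
    if model == "random-forest":
        return RandomForestClassifier(n_estimators=50, random_state=seed)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def _scores(fitted, X) -> np.ndarray:
    if hasattr(fitted, "decision_function"):
        return fitted.decision_function(X)
    return fitted.predict_proba(X)[:, 1]


def decode_statemap(coords: np.ndarray, labels: np.ndarray,
                    model: str = "svm-rbf", seed: int = 0,
                    feature_set: str = "statemap",
                    n_boot: int = 1000) -> DecodingResult:
    """Fit one decoder on the pooled epochs and score its AUC with a CI."""
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    if X.shape[0] < X.shape[1]:
        X = X.T
    y = _binary_labels(labels)
    clf = _make_model(model, seed)
    clf.fit(X, y)
    s = _scores(clf, X)
    auc = roc_auc_score(y, s)
    lo, hi = bootstrap_auc_ci(s, y, n_boot=n_boot, seed=seed)
    return DecodingResult(model=model, feature_set=feature_set, auc=float(auc),
                          ci_low=lo, ci_high=hi, n_epochs=len(y))


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        classes = np.unique(y.astype(str))
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        y = (y.astype(str) == classes[1]).astype(int)
    else:
        if len(np.unique(y)) != 2:
            raise ValueError("need exactly two classes")
        y = (y == np.max(y)).astype(int)
    return y


def bootstrap_auc_ci(scores: np.ndarray, labels: np.ndarray,
                     n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Percentile CI over case-resampled AUCs; degenerate resamples redrawn."""
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap repetitions")
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            n_redrawn += 1
        aucs[b] = roc_auc_score(yb, s[idx])
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap resamples")
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def decode_fullspectrum(features: np.ndarray, labels: np.ndarray,
                        seed: int = 0, model: str = "random-forest",
                        feature_set: str = "combined",
                        n_repeats: int = 100,
                        test_frac: float = 0.2) -> DecodingResult:
    """Repeated stratified 80/20 holdout AUC for high-dimensional features."""
    X = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    if len(y) < 5 * X.shape[1]:
        warnings.warn(
            f"{len(y)} epochs for {X.shape[1]} features; holdout AUCs may be "
            "optimistic or unstable")
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_frac,
                                      random_state=seed)
    aucs = []
    for tr, te in splitter.split(X, y):
        clf = _make_model(model, seed)
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _scores(clf, X[te])))
    aucs = np.asarray(aucs)
    return DecodingResult(model=model, feature_set=feature_set,
                          auc=float(aucs.mean()),
                          holdout_mean=float(aucs.mean()),
                          holdout_sd=float(aucs.std()),
                          n_epochs=len(y))
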