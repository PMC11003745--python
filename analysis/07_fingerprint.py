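#!/usr/bin/env python
"""Six-variable oscillatory fingerprint and group discrimination.

Assembles the per-subject fingerprint table, runs PCA, the regularized
linear discriminant with leave-one-out cross-validation, univariate
logistic-regression AUCs, and Ward clustering; writes the table and a JSON
report under results/.
"""

import argparse
import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from lfpstates import fingerprint, pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.parse_args()
    with open(ROOT / "scratch" / "subject_analyses.pkl", "rb") as f:
        analyses = list(pickle.load(f).values())
    fps = [fingerprint.extract_fingerprint(pipeline.fingerprint_features(a))
           for a in analyses]
    df = fingerprint.cohort_frame(fps)
    df.to_csv(ROOT / "results" / "fingerprints.csv", index=False)
    X = df[list(fingerprint.FEATURE_NAMES)].to_numpy()
    y = df["group"].to_numpy()

    pca = fingerprint.pca_project(X)
    lda = fingerprint.lda_classify(X, y)
    aucs = {f: round(fingerprint.univariate_auc(df[f], y), 3)
            for f in fingerprint.FEATURE_NAMES}
    subj_clust = fingerprint.hierarchical_cluster(X)
    var_clust = fingerprint.hierarchical_cluster(
        ((X - X.mean(0)) / X.std(0)).T, metric="correlation", z_score=False)

    report = {
        "n_subjects": int(len(y)),
        "explained_variance_ratio": [round(float(v), 4)
                                     for v in pca.explained_variance_ratio],
        "pc1_group_correlation": round(float(abs(np.corrcoef(
            pca.scores[:, 0], (y == "ELS").astype(float))[0, 1])), 3),
        "lda_train_accuracy": lda.train_accuracy,
        "lda_loocv_accuracy": lda.loocv_accuracy,
        "univariate_auc": aucs,
        "subject_cluster_k": int(subj_clust.k),
        "subject_cluster_labels": {s: int(c) for s, c in
                                   zip(df["subject"], subj_clust.labels)},
        "variable_leaf_order": [fingerprint.FEATURE_NAMES[i]
                                for i in var_clust.leaf_order],
    }
    with open(ROOT / "results" / "fingerprint_report.json", "w") as f:
        json.dump(report, f, indent=2)
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
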