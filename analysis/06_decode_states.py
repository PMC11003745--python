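#!/usr/bin/env python
"""REM vs ACT decoding per experimental group.

Pools each group's epochs and evaluates the state-map decoders (linear SVM,
RBF SVM, random forest) and the whole-spectrum random forest; writes the
results table under results/.
"""

import argparse
import pickle
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from lfpstates import decoding, pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")
    with open(ROOT / "scratch" / "subject_analyses.pkl", "rb") as f:
        analyses = list(pickle.load(f).values())
    rows = []
    for group in ("CTRL", "ELS"):
        Xm, ym = pipeline.pooled_rem_act(analyses, group, "statemap")
        for model in ("svm-linear", "svm-rbf", "random-forest"):
            r = decoding.decode_fullspectrum(Xm, ym, seed=args.seed,
                                             model=model, n_repeats=50,
                                             feature_set="statemap")
            rows.append({"group": group, "model": model,
                         "feature_set": "statemap",
                         "auc": round(r.holdout_mean, 3),
                         "auc_sd": round(r.holdout_sd, 3),
                         "n_epochs": r.n_epochs})
        for block in ("pfc-power", "hpc-power", "coherence", "combined"):
            Xs, ys = pipeline.pooled_rem_act(analyses, group, block)
            r = decoding.decode_fullspectrum(Xs, ys, seed=args.seed,
                                             n_repeats=50, feature_set=block)
            rows.append({"group": group, "model": "random-forest",
                         "feature_set": block,
                         "auc": round(r.holdout_mean, 3),
                         "auc_sd": round(r.holdout_sd, 3),
                         "n_epochs": r.n_epochs})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "decoding.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
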