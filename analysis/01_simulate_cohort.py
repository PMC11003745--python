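#!/usr/bin/env python
"""Generate the demonstration cohort (CTRL and ELS presets).

Writes recordings as HDF5 under scratch/cohort/ (large, regenerable) and a
plain-text manifest plus ground-truth event tables under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lfpstates import io, synth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-ctrl", type=int, default=3)
    ap.add_argument("--n-els", type=int, default=4)
    ap.add_argument("--duration", type=float, default=1800.0)
    args = ap.parse_args()

    out_rec = ROOT / "scratch" / "cohort"
    out_rec.mkdir(parents=True, exist_ok=True)
    out_res = ROOT / "results"
    out_res.mkdir(exist_ok=True)

    cohort = synth.make_cohort(args.n_ctrl, args.n_els, seed=args.seed,
                               duration_s=args.duration)
    manifest = []
    truths = {}
    for rec, truth in cohort:
        path = out_rec / f"{rec.subject}.h5"
        io.save_recording(path, rec)
        pd.DataFrame({"epoch_start_s": 5.0 * pd.RangeIndex(len(truth.states_5s)),
                      "state": truth.states_5s}).to_csv(
            out_rec / f"{rec.subject}_truth_states.csv", index=False)
        manifest.append({"subject": rec.subject, "group": rec.group,
                         "fs": rec.fs, "duration_s": rec.duration,
                         "n_swd_events": len(truth.swd_intervals),
                         "file": str(path.relative_to(ROOT))})
        truths[rec.subject] = [[round(s, 3), round(e, 3)]
                               for s, e in truth.swd_intervals]
    pd.DataFrame(manifest).to_csv(out_res / "cohort_manifest.csv", index=False)
    with open(out_res / "cohort_true_swd_events.json", "w") as f:
        json.dump(truths, f, indent=1)
    n_swd = sum(m["n_swd_events"] > 0 for m in manifest)
    print(f"wrote {len(manifest)} subjects ({args.n_ctrl} CTRL, "
          f"{args.n_els} ELS); {n_swd} subjects carry injected SWDs")


if __name__ == "__main__":
    main()
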