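#!/usr/bin/env python
"""Detect spike-wave discharges in the cohort PFC channels.

Writes the curated event table and the per-state occurrence summary under
results/, and scores detections against the injected ground truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lfpstates import io, swd

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.parse_args()
    manifest = pd.read_csv(ROOT / "results" / "cohort_manifest.csv")
    with open(ROOT / "results" / "cohort_true_swd_events.json") as f:
        truths = json.load(f)
    all_events = []
    summary = []
    for _, m in manifest.iterrows():
        rec = io.load_recording(ROOT / m["file"])
        tfr = swd.stft_magnitude(rec.pfc, rec.fs)
        events = swd.curate_events(swd.detect_swd(tfr), tfr)
        hyp = pd.read_csv(ROOT / "scratch" / "hypnograms"
                          / f"{m['subject']}_hypnogram_5s.csv")
        stats = swd.swd_state_stats(events, hyp["state"].to_numpy())
        match = swd.match_events(events,
                                 [tuple(t) for t in truths[m["subject"]]])
        df = swd.events_to_frame(events)
        df.insert(0, "subject", m["subject"])
        all_events.append(df)
        summary.append({
            "subject": m["subject"], "group": m["group"],
            "n_events": stats["n_events"],
            "swd_negative": stats["swd_negative"],
            "mean_duration_s": round(stats["mean_duration_s"], 3)
            if stats["n_events"] else None,
            "nrem_rate_per_min": round(stats["rate_per_min"].get("NREM", 0), 3),
            "precision_vs_truth": round(match["precision"], 3),
            "recall_vs_truth": round(match["recall"], 3),
        })
        print(f"{m['subject']:8s}: {stats['n_events']} events "
              f"(P={match['precision']:.2f} R={match['recall']:.2f})")
    pd.concat(all_events, ignore_index=True).to_csv(
        ROOT / "results" / "swd_events.csv", index=False)
    pd.DataFrame(summary).to_csv(ROOT / "results" / "swd_summary.csv",
                                 index=False)


if __name__ == "__main__":
    main()
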