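"""Subject-level orchestration: staging, spectral metrics, state map, and the
six-feature fingerprint from one recording.

Per-state spectral quantities are computed on the 30 s hypnogram grid, each
30 s epoch subdivided into ten 3 s epochs for Welch estimation; per-state
estimates average epoch-level spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spectral, staging, statemap, swd
from .bands import FREQ_BANDS
from .io import Recording
from .specparam import parametrize_spectrum
from .spectral import SpectralEstimate

SUB_EPOCH_S = 3.0


@dataclass
class SubjectAnalysis:
    """Everything downstream group analyses need from one subject."""

    subject: str
    group: str
    hypnogram: staging.Hypnogram
    features: dict = field(default_factory=dict)       # six fingerprint elements
    state_coherence: dict = field(default_factory=dict)  # state -> band MSC
    map: statemap.StateMap | None = None
    map_labels: np.ndarray | None = None               # 30 s labels for the map
    # REM/ACT whole-spectrum decoder blocks (per 30 s epoch)
    spectrum_features: dict = field(default_factory=dict)
    swd_events: list = field(default_factory=list)
    swd_stats: dict = field(default_factory=dict)


def _sub_epochs(x: np.ndarray, fs: float, epoch_idx: np.ndarray) -> np.ndarray:
    """Ten 3 s sub-epochs for each 30 s epoch index, stacked."""
    spe30 = int(round(30 * fs))
    spe3 = int(round(SUB_EPOCH_S * fs))
    segs = []
    for i in epoch_idx:
        base = i * spe30
        for k in range(10):
            segs.append(x[base + k * spe3: base + (k + 1) * spe3])
    return np.asarray(segs)


def analyze_subject(rec: Recording, seed: int = 0,
                    detect_swds: bool = False,
                    hypnogram: staging.Hypnogram | None = None) -> SubjectAnalysis:
    """Run the full per-subject pipeline on one recording."""
    fs = rec.fs
    if hypnogram is None:
        feats = staging.compute_epoch_features(rec)
        seeds = staging.seed_labels(feats)
        hypnogram = staging.train_and_classify(feats, seeds)
    labels30 = hypnogram.labels_30s.astype(str)
    out = SubjectAnalysis(subject=rec.subject, group=rec.group,
                          hypnogram=hypnogram)

    idx_by_state = {s: np.flatnonzero(labels30 == s)
                    for s in ("ACT", "QWK", "NREM", "REM")}

    # one PSD per 3 s sub-epoch per region, reused by every stage below
    all_idx = np.arange(len(labels30))
    segs3 = {region: _sub_epochs(getattr(rec, region), fs, all_idx)
             for region in ("pfc", "hpc")}
    psd3 = {region: spectral.welch_psd(segs3[region], fs)
            for region in ("pfc", "hpc")}
    labels3 = np.repeat(labels30, 10)

    def state_psd(state: str, region: str) -> SpectralEstimate:
        est = psd3[region]
        return SpectralEstimate(est.freqs, est.values[labels3 == state],
                                kind="psd", meta=est.meta)

    psd_by_state: dict[str, dict[str, SpectralEstimate]] = {
        state: {region: state_psd(state, region) for region in ("pfc", "hpc")}
        for state, idx in idx_by_state.items() if len(idx)
    }

    # feature 1: HPC theta relative power in ACT
    if "ACT" in psd_by_state:
        rel = spectral.relative_power(psd_by_state["ACT"]["hpc"])
        out.features["hpc_theta_rel_power_act"] = float(
            spectral.band_power(rel, "theta").mean())

    # one MSC per 3 s sub-epoch, shared by the per-state summaries and the
    # whole-spectrum decoder blocks
    coh3 = spectral.msc_coherence(segs3["hpc"], segs3["pfc"], fs)

    # per-state theta coherence; features 2 and 5. A state that vanished in
    # the 30 s consolidation falls back to its 5 s-grid predicted epochs.
    labels5 = hypnogram.labels_5s.astype(str)
    spe5 = int(round(5 * fs))
    for state in ("REM", "QWK", "ACT"):
        if len(idx_by_state[state]) > 0:
            mean_coh = coh3.values[labels3 == state].mean(axis=0)
        else:
            idx5 = np.flatnonzero(labels5 == state)
            if len(idx5) == 0:
                continue
            h = np.stack([rec.hpc[i * spe5: i * spe5 + int(3 * fs)]
                          for i in idx5])
            p = np.stack([rec.pfc[i * spe5: i * spe5 + int(3 * fs)]
                          for i in idx5])
            cohf = spectral.msc_coherence(h, p, fs)
            mean_coh = np.atleast_2d(cohf.values).mean(axis=0)
        out.state_coherence[state] = float(spectral.band_mean(
            SpectralEstimate(coh3.freqs, mean_coh), "theta"))
    if len(out.state_coherence) == 3:
        out.features["theta_coherence_entropy"] = spectral.coherence_entropy(
            [out.state_coherence[s] for s in ("REM", "QWK", "ACT")])
    if "REM" in out.state_coherence:
        out.features["rem_theta_coherence_z"] = float(
            spectral.fisher_z(out.state_coherence["REM"]))

    # feature 3: PFC aperiodic exponent in ACT (fit of the mean ACT spectrum)
    if "ACT" in psd_by_state:
        est = psd_by_state["ACT"]["pfc"]
        fit = parametrize_spectrum(est.freqs, est.values.mean(axis=0))
        out.features["pfc_exponent_act"] = fit.exponent

    # feature 4: PFC theta-high-gamma amplitude correlation in ACT
    if len(idx_by_state["ACT"]) > 0:
        comod = spectral.amplitude_comodulogram(segs3["pfc"][labels3 == "ACT"], fs)
        out.features["pfc_theta_gamma_r_act"] = spectral.theta_gamma_correlation(comod)

    # state map on the 3 s spectral grid; feature 6
    hpc_r = statemap.spectral_ratios(psd3["hpc"])
    pfc_r = statemap.spectral_ratios(psd3["pfc"])
    out.map = statemap.build_state_map(hpc_r, pfc_r)
    out.map_labels = labels3
    # distance fallbacks: if a state lost every 30 s modal vote, relabel the
    # map points from the 5 s hypnogram; if IS exclusion empties a state,
    # include the flagged points
    dist_labels = labels3
    if not (len(idx_by_state["REM"]) and len(idx_by_state["ACT"])):
        t3 = np.arange(len(labels3)) * SUB_EPOCH_S + SUB_EPOCH_S / 2
        idx5 = np.minimum((t3 // 5).astype(int), len(labels5) - 1)
        dist_labels = labels5[idx5]
    if np.any(dist_labels == "REM") and np.any(dist_labels == "ACT"):
        try:
            dist = statemap.rem_act_distance(out.map, dist_labels, seed=seed)
        except ValueError:
            dist = statemap.rem_act_distance(out.map, dist_labels, seed=seed,
                                             exclude_is=False)
        out.features["rem_act_distance"] = dist["mean_distance"]

    # whole-spectrum decoder blocks for REM/ACT 30 s epochs
    psd30 = {region: _epoch_mean(psd3[region], len(labels30))
             for region in ("pfc", "hpc")}
    coh30 = _epoch_mean(coh3, len(labels30))
    out.spectrum_features = _spectrum_blocks(idx_by_state, psd30["pfc"],
                                             psd30["hpc"], coh30)

    if detect_swds:
        tfr = swd.stft_magnitude(rec.pfc, fs)
        events = swd.curate_events(swd.detect_swd(tfr), tfr)
        out.swd_events = events
        out.swd_stats = swd.swd_state_stats(
            events, hypnogram.labels_5s[: (len(labels30) * 6)])
    return out


def _epoch_mean(est3: SpectralEstimate, n30: int) -> SpectralEstimate:
    """Per-30 s-epoch PSD: mean over the epoch's ten 3 s sub-epoch PSDs."""
    vals = est3.values.reshape(n30, 10, -1).mean(axis=1)
    return SpectralEstimate(est3.freqs, vals, kind="psd", meta=est3.meta)


def _spectrum_blocks(idx_by_state, psd_pfc, psd_hpc, coh30) -> dict:
    """1-55 Hz (0.5 Hz bins) power and coherence features per REM/ACT epoch."""
    if len(idx_by_state["REM"]) == 0 or len(idx_by_state["ACT"]) == 0:
        return {}
    order = np.sort(np.concatenate([idx_by_state["REM"], idx_by_state["ACT"]]))
    labels = np.where(np.isin(order, idx_by_state["REM"]), "REM", "ACT")
    f = psd_pfc.freqs
    band = (f >= 1.0) & (f <= 55.0)
    return {
        "labels": labels,
        "pfc_power": psd_pfc.values[order][:, band],
        "hpc_power": psd_hpc.values[order][:, band],
        "coherence": coh30.values[order][:, band],
        "freqs": f[band],
    }


def fingerprint_features(analysis: SubjectAnalysis) -> dict:
    """Feature dict (plus identifiers) for fingerprint assembly."""
    return {"subject": analysis.subject, "group": analysis.group,
            **analysis.features}


def analyze_cohort(cohort, seed: int = 0,
                   detect_swds: bool = False) -> list[SubjectAnalysis]:
    """Run the per-subject pipeline over a list of (Recording, GroundTruth)."""
    return [analyze_subject(rec, seed=seed + i, detect_swds=detect_swds)
            for i, (rec, _) in enumerate(cohort)]


def pooled_rem_act(analyses, group: str, feature: str = "statemap"):
    """Pool one group's REM/ACT epochs for decoding.

    ``feature`` selects the state-map coordinates or one of the
    whole-spectrum blocks ('pfc-power' | 'hpc-power' | 'coherence' |
    'combined').
    """
    xs, ys = [], []
    for ana in analyses:
        if ana.group != group:
            continue
        if feature == "statemap":
            sel = np.isin(ana.map_labels, ["REM", "ACT"]) & ~ana.map.is_flags
            xs.append(ana.map.coords[sel])
            ys.append(ana.map_labels[sel])
        else:
            sf = ana.spectrum_features
            if not sf:
                continue
            blocks = {"pfc-power": ["pfc_power"], "hpc-power": ["hpc_power"],
                      "coherence": ["coherence"],
                      "combined": ["pfc_power", "hpc_power", "coherence"]}
            xs.append(np.hstack([sf[b] for b in blocks[feature]]))
            ys.append(sf["labels"])
    if not xs:
        raise ValueError(f"no pooled epochs for group {group!r}")
    return np.vstack(xs), np.concatenate(ys)
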