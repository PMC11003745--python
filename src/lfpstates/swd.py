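"""Spike-wave discharge (SWD) detection on the PFC channel.

The detector thresholds the band-averaged magnitude of a short-time Fourier
transform: 250 ms windows with 50 % overlap over 3-70 Hz, scored per frame as
the unweighted mean of the mean magnitudes within the 4.4-16.4, 17.6-32.8 and
35.1-55 Hz bands. Frames above mean + 1.5 SD of the score (over the whole
recording) seed events, consecutive suprathreshold frames merge, and
boundaries expand outward to the nearest frames below mean + 1 SD. Expert
curation is replaced by rule-based duration and rhythmicity criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCORE_BANDS = ((4.4, 16.4), (17.6, 32.8), (35.1, 55.0))


@dataclass
class TimeFrequency:
    """STFT magnitude matrix restricted to 3-70 Hz."""

    times_s: np.ndarray     # frame start times
    freqs: np.ndarray
    mags: np.ndarray        # (n_frames, n_freqs)
    window_s: float
    hop_s: float


@dataclass
class SWDEvent:
    start_s: float
    end_s: float
    peak_score: float
    state: str | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def stft_magnitude(pfc: np.ndarray, fs: float, window_s: float = 0.25,
                   overlap: float = 0.5, fmin: float = 3.0,
                   fmax: float = 70.0) -> TimeFrequency:
    """Per-frame FFT magnitudes, 3-70 Hz, mean removed per window.

    Per-window mean removal keeps DC leakage from dominating the 3-4 Hz edge.
    """
    if fs < 200:
        raise ValueError("SWD detection needs fs >= 200 Hz")
    nper = int(round(window_s * fs))
    if len(pfc) < nper:
        raise ValueError("signal shorter than one STFT window")
    hop = int(round(nper * (1 - overlap)))
    frames = np.lib.stride_tricks.sliding_window_view(pfc, nper)[::hop]
    frames = frames - frames.mean(axis=-1, keepdims=True)
    mags = np.abs(np.fft.rfft(frames, axis=-1))
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    times = np.arange(frames.shape[0]) * hop / fs
    return TimeFrequency(times_s=times, freqs=freqs[sel], mags=mags[:, sel],
                         window_s=window_s, hop_s=hop / fs)


def band_score(tfr: TimeFrequency,
               bands: tuple = SCORE_BANDS) -> np.ndarray:
    """Per-frame score: unweighted mean of within-band mean magnitudes."""
    parts = []
    for lo, hi in bands:
        sel = (tfr.freqs >= lo) & (tfr.freqs <= hi)
        parts.append(tfr.mags[:, sel].mean(axis=-1))
    return np.mean(parts, axis=0)


def detect_swd(tfr: TimeFrequency, k_on: float = 1.5,
               k_off: float = 1.0) -> list[SWDEvent]:
    """Threshold the band score at mean + k_on SD; expand to mean + k_off SD."""
    score = band_score(tfr)
    mu, sd = score.mean(), score.std()
    on_thresh = mu + k_on * sd
    off_thresh = mu + k_off * sd
    above = score > on_thresh
    events: list[tuple[int, int]] = []
    i = 0
    n = len(score)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            lo = i
            while lo > 0 and score[lo - 1] >= off_thresh:
                lo -= 1
            hi = j
            while hi + 1 < n and score[hi + 1] >= off_thresh:
                hi += 1
            if events and lo <= events[-1][1] + 1:
                events[-1] = (events[-1][0], hi)
            else:
                events.append((lo, hi))
            i = hi + 1
        else:
            i += 1
    out = []
    for lo, hi in events:
        start = tfr.times_s[lo]
        end = tfr.times_s[hi] + tfr.window_s
        out.append(SWDEvent(start_s=float(start), end_s=float(end),
                            peak_score=float(score[lo:hi + 1].max())))
    return out


def _event_profile(tfr: TimeFrequency, event: SWDEvent) -> np.ndarray | None:
    sel = (tfr.times_s + tfr.window_s > event.start_s) & (tfr.times_s < event.end_s)
    if not sel.any():
        return None
    return tfr.mags[sel].mean(axis=0)


def dominant_frequency(tfr: TimeFrequency, event: SWDEvent) -> float:
    """Frequency bin with the largest mean magnitude across the event frames."""
    prof = _event_profile(tfr, event)
    if prof is None:
        return np.nan
    return float(tfr.freqs[np.argmax(prof)])


def harmonic_ratio(tfr: TimeFrequency, event: SWDEvent) -> float:
    """Second-harmonic to fundamental magnitude ratio of an event.

    Spike-wave discharges are sharp, so their spectra carry strong harmonics
    of the fundamental; ordinary theta is near-sinusoidal and does not.
    """
    prof = _event_profile(tfr, event)
    if prof is None:
        return 0.0
    k = int(np.argmax(prof))
    f_dom = tfr.freqs[k]
    k2 = int(np.argmin(np.abs(tfr.freqs - 2 * f_dom)))
    if abs(tfr.freqs[k2] - 2 * f_dom) > (tfr.freqs[1] - tfr.freqs[0]):
        return 0.0
    return float(prof[k2] / prof[k]) if prof[k] > 0 else 0.0


def curate_events(events: list[SWDEvent], tfr: TimeFrequency,
                  min_duration_s: float = 1.0,
                  min_cycles: float = 5.0,
                  min_harmonic_ratio: float = 0.45) -> list[SWDEvent]:
    """Rule-based surrogate for expert sorting.

    Keeps events at least ``min_duration_s`` long, spanning at least
    ``min_cycles`` cycles of their dominant frequency, and whose spectrum
    shows spike-like harmonic content (second-harmonic / fundamental
    magnitude ratio of at least ``min_harmonic_ratio``) — sustained normal
    theta crosses the detection threshold too but is near-sinusoidal and
    fails this rule.
    """
    kept = []
    for ev in events:
        if ev.duration_s < min_duration_s:
            continue
        f_dom = dominant_frequency(tfr, ev)
        if np.isnan(f_dom) or ev.duration_s * f_dom < min_cycles:
            continue
        if harmonic_ratio(tfr, ev) < min_harmonic_ratio:
            continue
        kept.append(ev)
    return kept


def swd_state_stats(events: list[SWDEvent], labels_5s: np.ndarray,
                    epoch_s: float = 5.0) -> dict:
    """Per-state event counts and rates; events assigned by onset epoch."""
    labels = np.asarray(labels_5s).astype(str)
    span_s = len(labels) * epoch_s
    states = sorted(set(labels))
    minutes_in_state = {s: float(np.sum(labels == s)) * epoch_s / 60.0
                        for s in states}
    counts = {s: 0 for s in states}
    for ev in events:
        if not 0 <= ev.start_s < span_s:
            raise ValueError(
                f"event onset {ev.start_s} s outside hypnogram span {span_s} s")
        onset_state = labels[int(ev.start_s // epoch_s)]
        ev.state = onset_state
        counts[onset_state] += 1
    rates = {s: (counts[s] / minutes_in_state[s] if minutes_in_state[s] > 0 else 0.0)
             for s in states}
    durations = [ev.duration_s for ev in events]
    return {
        "counts": counts,
        "minutes_in_state": minutes_in_state,
        "rate_per_min": rates,
        "n_events": len(events),
        "total_minutes": float(np.sum(durations)) / 60.0,
        "mean_duration_s": float(np.mean(durations)) if durations else np.nan,
        "swd_negative": len(events) == 0,
    }


def events_to_frame(events: list[SWDEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"onset_s": ev.start_s, "offset_s": ev.end_s,
          "duration_s": ev.duration_s, "peak_score": ev.peak_score,
          "state": ev.state} for ev in events]
    )


def match_events(detected: list[SWDEvent],
                 truth: list[tuple[float, float]],
                 min_overlap_frac: float = 0.3) -> dict:
    """Precision/recall of detections against injected intervals.

    A detection matches a true event when their overlap covers at least
    ``min_overlap_frac`` of the true duration; each true event can be claimed
    once. Boundary error = mean of |onset error| and |offset error| per match.
    """
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    boundary_errs = []
    for ev in detected:
        best, best_ov = -1, 0.0
        for k, (s, e) in enumerate(truth):
            if used[k]:
                continue
            ov = max(0.0, min(ev.end_s, e) - max(ev.start_s, s))
            if ov > best_ov:
                best, best_ov = k, ov
        if best >= 0 and best_ov >= min_overlap_frac * (truth[best][1] - truth[best][0]):
            used[best] = True
            tp += 1
            s, e = truth[best]
            boundary_errs.append(0.5 * (abs(ev.start_s - s) + abs(ev.end_s - e)))
    fp = len(detected) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_true": len(truth),
        "n_detected": len(detected),
        "median_boundary_error_s": float(np.median(boundary_errs)) if boundary_errs else np.nan,
    }
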