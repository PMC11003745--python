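"""Semi-supervised sleep-wake staging of 5 s epochs into ACT/QWK/NREM/REM.

The pipeline mirrors standard rodent polysomnography practice: multitaper
band power per 5 s epoch (HPC theta 4.5-12 Hz, PFC delta 0.7-4 Hz, EMG
100-200 Hz), bootstrap seed labels from the extreme quartiles of the decision
features, then a cascade of three radial-basis SVMs — (1) wake vs sleep on
EMG power, (2) REM vs NREM on the theta/delta ratio among sleep epochs,
(3) ACT vs QWK on the theta/delta ratio among wake epochs. Six 5 s epochs
are consolidated into one 30 s hypnogram label by majority, ties broken by
the summed classifier margin.

The bootstrap-seeding rule replaces manual scoring: a two-component mixture
split of log EMG power seeds the wake/sleep classes, and mixture splits of
the log theta/delta ratio within each pool seed REM/NREM and ACT/QWK. The
mixture split places each cut at the Bayes boundary of a 1-D two-Gaussian
fit, which stays correct even when one state covers far less than a quartile
of its pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows
from sklearn.svm import SVC

from .bands import FREQ_BANDS

EPOCH_S = 5.0
MULTITAPER_NW = 2.5
MULTITAPER_K = 4


@dataclass
class EpochFeatures:
    """Per-5 s-epoch staging features."""

    hpc_theta: np.ndarray     # HPC power, 4.5-12 Hz
    pfc_delta: np.ndarray     # PFC power, 0.7-4 Hz
    emg: np.ndarray           # EMG power, 100-200 Hz

    @property
    def theta_delta(self) -> np.ndarray:
        return self.hpc_theta / self.pfc_delta

    @property
    def n_epochs(self) -> int:
        return len(self.emg)


@dataclass
class Hypnogram:
    """Brain-state labels on the 5 s grid and the consolidated 30 s grid."""

    labels_5s: np.ndarray
    margins_5s: np.ndarray
    labels_30s: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))


def _multitaper_band_power(epochs: np.ndarray, fs: float,
                           bands: list[tuple[float, float]]) -> list[np.ndarray]:
    """Mean multitaper PSD within each band, per epoch (DPSS, NW=2.5, K=4)."""
    n = epochs.shape[-1]
    tapers = windows.dpss(n, MULTITAPER_NW, Kmax=MULTITAPER_K)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.zeros((epochs.shape[0], freqs.size))
    for taper in tapers:
        spec = np.fft.rfft(epochs * taper, axis=-1)
        psd += np.abs(spec) ** 2
    psd /= MULTITAPER_K * fs
    psd[:, 1:-1] *= 2  # one-sided density
    out = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs <= hi)
        out.append(psd[:, sel].mean(axis=-1))
    return out


def compute_epoch_features(recording) -> EpochFeatures:
    """Multitaper staging features on non-overlapping 5 s epochs."""
    fs = recording.fs
    if fs < 400:
        raise ValueError("staging EMG band 100-200 Hz needs fs >= 400 Hz")
    spe = int(round(EPOCH_S * fs))
    n_ep = recording.n_samples // spe
    if n_ep < 1:
        raise ValueError("recording shorter than one 5 s epoch")

    def epochs_of(x):
        return x[: n_ep * spe].reshape(n_ep, spe)

    (hpc_theta,) = _multitaper_band_power(
        epochs_of(recording.hpc), fs, [FREQ_BANDS["staging_theta"]])
    (pfc_delta,) = _multitaper_band_power(
        epochs_of(recording.pfc), fs, [FREQ_BANDS["staging_delta"]])
    (emg,) = _multitaper_band_power(
        epochs_of(recording.emg), fs, [FREQ_BANDS["emg"]])
    return EpochFeatures(hpc_theta=hpc_theta, pfc_delta=pfc_delta, emg=emg)


MIN_SEEDS_PER_CLASS = 10


def seed_labels(features: EpochFeatures) -> dict[str, np.ndarray]:
    """Bootstrap labels from mixture splits of the staging features.

    Returns a dict mapping each state to the epoch indices seeded for it.
    """
    n = features.n_epochs
    if n < 200:
        warnings.warn(f"only {n} epochs; seed quartiles may be unstable")
    log_emg = np.log(features.emg)
    log_ratio = np.log(features.theta_delta)
    if np.ptp(log_emg) < 1e-12 or np.ptp(log_ratio) < 1e-12:
        raise ValueError("constant features: no separable extremes to seed from")
    # two-component mixture splits rather than fixed quartiles: quartile
    # seeding structurally mislabels whenever a class holds less than 25 %
    # of the recording (common for wake fraction and for REM within sleep)
    wake_mask = _mixture_split(log_emg)
    wake_idx = np.flatnonzero(wake_mask)
    sleep_idx = np.flatnonzero(~wake_mask)

    def split_by_ratio(idx):
        high = _mixture_split(log_ratio[idx])
        return idx[~high], idx[high]

    nrem_idx, rem_idx = split_by_ratio(sleep_idx)
    qwk_idx, act_idx = split_by_ratio(wake_idx)
    seeds = {"ACT": act_idx, "QWK": qwk_idx, "NREM": nrem_idx, "REM": rem_idx}
    for state, idx in seeds.items():
        if len(idx) < MIN_SEEDS_PER_CLASS:
            raise ValueError(
                f"only {len(idx)} seed epochs for {state} "
                f"(need >= {MIN_SEEDS_PER_CLASS}); record longer"
            )
    return seeds


def _mixture_split(values: np.ndarray) -> np.ndarray:
    """High-side mask of a two-component 1-D Gaussian-mixture posterior split."""
    from sklearn.mixture import GaussianMixture
    v = values[:, None]
    gmm = GaussianMixture(n_components=2, random_state=0)
    gmm.fit(v)
    hi = int(np.argmax(gmm.means_.ravel()))
    return gmm.predict_proba(v)[:, hi] > 0.5


def _fit_stage(x_train: np.ndarray, y_train: np.ndarray, x_all: np.ndarray):
    """One cascade stage: RBF-SVM on a single log-scaled standardized feature."""
    mu, sd = x_train.mean(), x_train.std()
    if sd == 0:
        raise ValueError("degenerate stage feature (zero variance)")
    clf = SVC(kernel="rbf", C=1.0, gamma="scale")
    clf.fit(((x_train - mu) / sd)[:, None], y_train)
    margin = clf.decision_function(((x_all - mu) / sd)[:, None])
    pred = clf.classes_[(margin > 0).astype(int)]
    return pred, margin


def train_and_classify(features: EpochFeatures,
                       seeds: dict[str, np.ndarray]) -> Hypnogram:
    """Cascade of three binary RBF-SVM classifiers over the staging features.

    Stage 1 (wake vs sleep, EMG) trains on the quartile seeds. Stages 2 and 3
    then re-derive their bootstrap labels from the *predicted* sleep and wake
    pools (extreme theta/delta quartiles within each pool): the raw EMG
    quartiles over-represent the extreme states (ACT among wake, REM among
    sleep), so seeding the within-pool discriminations from the full predicted
    pools keeps their decision boundaries centered.
    """
    log_emg = np.log(features.emg)
    log_ratio = np.log(features.theta_delta)
    n = features.n_epochs

    # stage 1: wake vs sleep on EMG power
    idx_wake = np.concatenate([seeds["ACT"], seeds["QWK"]])
    idx_sleep = np.concatenate([seeds["NREM"], seeds["REM"]])
    x1 = np.concatenate([log_emg[idx_wake], log_emg[idx_sleep]])
    y1 = np.array(["wake"] * len(idx_wake) + ["sleep"] * len(idx_sleep))
    pred1, margin1 = _fit_stage(x1, y1, log_emg)
    is_wake = pred1 == "wake"

    def pool_seeds(pool_idx, low_label, high_label):
        # bimodality-aware bootstrap: a two-component mixture split of the
        # pooled ratio keeps seed purity even when one state holds far less
        # than a quartile of its pool (fixed quartiles structurally mislabel
        # in that case) and places the cut at the Bayes boundary even for
        # unequal spreads
        high = _mixture_split(log_ratio[pool_idx])
        return {low_label: pool_idx[~high], high_label: pool_idx[high]}

    # stage 2: REM vs NREM among predicted sleep epochs, on theta/delta
    s2 = pool_seeds(np.flatnonzero(~is_wake), "NREM", "REM")
    x2 = np.concatenate([log_ratio[s2["REM"]], log_ratio[s2["NREM"]]])
    y2 = np.array(["REM"] * len(s2["REM"]) + ["NREM"] * len(s2["NREM"]))
    pred2, margin2 = _fit_stage(x2, y2, log_ratio)

    # stage 3: ACT vs QWK among predicted wake epochs, on theta/delta
    s3 = pool_seeds(np.flatnonzero(is_wake), "QWK", "ACT")
    x3 = np.concatenate([log_ratio[s3["ACT"]], log_ratio[s3["QWK"]]])
    y3 = np.array(["ACT"] * len(s3["ACT"]) + ["QWK"] * len(s3["QWK"]))
    pred3, margin3 = _fit_stage(x3, y3, log_ratio)

    labels = np.empty(n, dtype=object)
    margins = np.empty(n)
    labels[~is_wake] = pred2[~is_wake]
    margins[~is_wake] = np.abs(margin2[~is_wake])
    labels[is_wake] = pred3[is_wake]
    margins[is_wake] = np.abs(margin3[is_wake])
    hyp = Hypnogram(labels_5s=labels, margins_5s=margins)
    hyp.labels_30s = consolidate_epochs(labels, margins)
    return hyp


def consolidate_epochs(labels_5s: np.ndarray,
                       margins: np.ndarray | None = None) -> np.ndarray:
    """30 s labels: modal label of each group of six 5 s epochs.

    Ties are broken by the largest summed classifier margin among the tied
    labels (without margins, by the first tied label in canonical order).
    """
    labels_5s = np.asarray(labels_5s, dtype=object)
    if margins is None:
        margins = np.ones(len(labels_5s))
    n30 = len(labels_5s) // 6
    out = np.empty(n30, dtype=object)
    for i in range(n30):
        grp = labels_5s[6 * i: 6 * i + 6]
        mg = margins[6 * i: 6 * i + 6]
        uniq, counts = np.unique(grp.astype(str), return_counts=True)
        top = counts.max()
        tied = uniq[counts == top]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            sums = [mg[grp.astype(str) == lab].sum() for lab in tied]
            out[i] = tied[int(np.argmax(sums))]
    return out


def staging_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    n = min(len(pred), len(truth))
    return float(np.mean(np.asarray(pred[:n]).astype(str)
                         == np.asarray(truth[:n]).astype(str)))


def sleep_architecture_stats(labels_5s: np.ndarray, epoch_s: float = EPOCH_S,
                             min_episode_s: float = 15.0,
                             block_s: float = 6 * 3600.0) -> dict:
    """Sleep-architecture summaries on the 5 s grid.

    Returns per-state mean consecutive-run duration (s), percent time,
    persistent-episode counts (runs lasting at least ``min_episode_s``), and
    percent awake (ACT+QWK) per ``block_s`` block.
    """
    labels = np.asarray(labels_5s).astype(str)
    if len(labels) == 0:
        raise ValueError("empty hypnogram")
    runs: list[tuple[str, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], i - start))
            start = i
    states = sorted(set(labels))
    mean_dur = {}
    episodes = {}
    for s in states:
        lens = [r * epoch_s for lab, r in runs if lab == s]
        mean_dur[s] = float(np.mean(lens))
        episodes[s] = int(sum(1 for d in lens if d >= min_episode_s))
    pct = {s: 100.0 * float(np.mean(labels == s)) for s in states}
    per_block = int(round(block_s / epoch_s))
    awake = np.isin(labels, ["ACT", "QWK"])
    pct_awake_blocks = [
        100.0 * float(np.mean(awake[i:i + per_block]))
        for i in range(0, len(labels), per_block)
    ]
    return {
        "mean_consecutive_s": mean_dur,
        "percent_time": pct,
        "persistent_episodes": episodes,
        "percent_awake_per_block": pct_awake_blocks,
    }
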