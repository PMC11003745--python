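"""Per-epoch spectral estimators: Welch PSD, relative/band power, coherence,
EMG power, lagged cross-correlation and its cross-spectrum, amplitude
comodulograms, and the theta-coherence entropy statistic.

Conventions shared by every estimator:

* PSDs and coherences use Welch's method with 1 s segments, 50 % overlap and
  Hamming windowing, zero-padded to a 0.5 Hz grid so that band edges such as
  4.5 or 55 Hz fall on bin centers. Band membership is by bin center, edges
  inclusive.
* Relative power normalizes each epoch's PSD to sum to 1 within 0.5-55 Hz.
* The cross-correlogram sign convention is negative lag = HPC precedes PFC,
  with coefficients normalized so both zero-lag autocorrelations equal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bands import FREQ_BANDS, REL_POWER_RANGE, band_edges
from .io import zero_phase_highpass, zero_phase_lowpass


@dataclass
class SpectralEstimate:
    """Frequency-indexed values (PSD, relative power, or squared coherence)."""

    freqs: np.ndarray
    values: np.ndarray          # (..., n_freqs); leading axes = epochs
    kind: str = "psd"
    meta: dict = field(default_factory=dict)


def _welch_params(fs: float) -> dict:
    nperseg = int(round(fs))
    return dict(window="hamming", nperseg=nperseg, noverlap=nperseg // 2,
                nfft=2 * nperseg, detrend="constant")


def welch_psd(x: np.ndarray, fs: float) -> SpectralEstimate:
    """One-sided Welch PSD on a 0.5 Hz grid (1 s Hamming segments, 50 % overlap).

    ``x`` may be 1-D (one epoch) or 2-D (epochs x samples); per-epoch PSDs are
    returned along the leading axis. Each epoch must span at least one 1 s
    segment.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < int(round(fs)):
        raise ValueError("epoch shorter than one 1 s Welch segment")
    params = _welch_params(fs)
    freqs, psd = sps.welch(x, fs=fs, axis=-1, **params)
    return SpectralEstimate(freqs=freqs, values=psd, kind="psd",
                            meta={"fs": fs, **params})


def relative_power(est: SpectralEstimate) -> SpectralEstimate:
    """Normalize each epoch's PSD to sum to 1 within 0.5-55 Hz."""
    lo, hi = REL_POWER_RANGE
    f = est.freqs
    if f[0] > lo or f[-1] < hi:
        raise ValueError(f"frequency grid does not cover {lo}-{hi} Hz")
    sel = (f >= lo) & (f <= hi)
    denom = est.values[..., sel].sum(axis=-1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("zero total power in the normalization range")
    return SpectralEstimate(freqs=f, values=est.values / denom,
                            kind="relative_power", meta=dict(est.meta))


def band_power(est: SpectralEstimate, band) -> np.ndarray:
    """Sum of values whose bin center lies inside the band (edges inclusive).

    ``band`` is a band name from the band table or an explicit (lo, hi) pair.
    """
    lo, hi = band_edges(band) if isinstance(band, str) else band
    sel = (est.freqs >= lo) & (est.freqs <= hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside {lo}-{hi} Hz")
    return est.values[..., sel].sum(axis=-1)


def band_mean(est: SpectralEstimate, band) -> np.ndarray:
    """Mean of values inside the band (used for coherence summaries)."""
    lo, hi = band_edges(band) if isinstance(band, str) else band
    sel = (est.freqs >= lo) & (est.freqs <= hi)
    return est.values[..., sel].mean(axis=-1)


def msc_coherence(x: np.ndarray, y: np.ndarray, fs: float) -> SpectralEstimate:
    """Magnitude-squared coherence per epoch, Welch cross/auto spectra.

    Epochs (rows of 2-D inputs) are estimated independently; averaging over
    the epochs of a state is the caller's responsibility (done on the squared
    coherence values). Raises if an epoch yields a single Welch segment, where
    coherence is identically one.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("paired epochs must have identical shape")
    params = _welch_params(fs)
    n_seg = (x.shape[-1] - params["noverlap"]) // (params["nperseg"] - params["noverlap"])
    if n_seg < 2:
        raise ValueError("coherence needs >= 2 Welch segments per epoch")
    freqs, pxx = sps.welch(x, fs=fs, axis=-1, **params)
    _, pyy = sps.welch(y, fs=fs, axis=-1, **params)
    _, pxy = sps.csd(x, y, fs=fs, axis=-1, **params)
    coh = np.abs(pxy) ** 2 / (pxx * pyy)
    return SpectralEstimate(freqs=freqs, values=np.squeeze(coh),
                            kind="coherence", meta={"fs": fs, **params})


def fisher_z(coherence_value):
    """Fisher z for squared coherence: atanh(sqrt(C))."""
    c = np.asarray(coherence_value, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("squared coherence must lie in [0, 1]")
    return np.arctanh(np.sqrt(c))


def emg_power(emg_epochs: np.ndarray, fs: float) -> np.ndarray:
    """Per-epoch EMG power: >30 Hz low-cut, then summed PSD within 30-200 Hz."""
    if fs < 400:
        raise ValueError("EMG band 30-200 Hz needs fs >= 400 Hz")
    x = zero_phase_highpass(np.atleast_2d(np.asarray(emg_epochs, float)), fs, 30.0)
    est = welch_psd(x, fs)
    sel = (est.freqs >= 30.0) & (est.freqs <= 200.0)
    df = est.freqs[1] - est.freqs[0]
    return np.squeeze(est.values[..., sel].sum(axis=-1) * df)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Normalized HPC-PFC cross-correlation; negative lag = HPC precedes PFC."""

    lags_ms: np.ndarray
    coefs: np.ndarray


def cross_correlation(hpc_epochs: np.ndarray, pfc_epochs: np.ndarray,
                      fs: float, max_lag_s: float = 1.0) -> Correlogram:
    """Mean cross-correlogram over epochs, 50 Hz low-passed inputs.

    Coefficients are normalized by the geometric mean of the zero-lag
    autocorrelations, so either channel's autocorrelogram equals 1 at lag 0.
    """
    h = np.atleast_2d(np.asarray(hpc_epochs, float))
    p = np.atleast_2d(np.asarray(pfc_epochs, float))
    if h.shape != p.shape:
        raise ValueError("paired epochs must have identical shape")
    n = h.shape[-1]
    if n < int(2 * fs):
        raise ValueError("cross-correlation epochs must be >= 2 s")
    max_lag = int(round(max_lag_s * fs))
    if max_lag >= n:
        raise ValueError("maximum lag exceeds epoch length")
    h = zero_phase_lowpass(h, fs, 50.0)
    p = zero_phase_lowpass(p, fs, 50.0)
    h = h - h.mean(axis=-1, keepdims=True)
    p = p - p.mean(axis=-1, keepdims=True)
    coefs = np.zeros(2 * max_lag + 1)
    for hi, pi in zip(h, p):
        # c[tau] = sum_t pfc(t) * hpc(t + tau): peak at -d when pfc lags by d
        full = sps.correlate(hi, pi, mode="full", method="fft")
        mid = n - 1
        c = full[mid - max_lag: mid + max_lag + 1]
        norm = np.sqrt(np.dot(hi, hi) * np.dot(pi, pi))
        coefs += c / norm if norm > 0 else c
    coefs /= len(h)
    lags_ms = np.arange(-max_lag, max_lag + 1) / fs * 1000.0
    return Correlogram(lags_ms=lags_ms, coefs=coefs)


def peak_in_window(cg: Correlogram, lo_ms: float = -80.0,
                   hi_ms: float = -20.0) -> tuple[float, float]:
    """Maximum coefficient within a lag window; returns (lag_ms, coefficient)."""
    if lo_ms < cg.lags_ms[0] or hi_ms > cg.lags_ms[-1]:
        raise ValueError("window outside the correlogram lag range")
    sel = (cg.lags_ms >= lo_ms) & (cg.lags_ms <= hi_ms)
    idx = np.flatnonzero(sel)
    k = idx[np.argmax(cg.coefs[idx])]
    return float(cg.lags_ms[k]), float(cg.coefs[k])


def cross_spectrum_of_correlogram(cg: Correlogram, fs: float) -> SpectralEstimate:
    """Welch PSD of the correlogram coefficients treated as a time series."""
    span_s = (cg.lags_ms[-1] - cg.lags_ms[0]) / 1000.0
    if span_s < 1.999:
        raise ValueError("correlogram must span -1 to 1 s")
    return welch_psd(cg.coefs, fs)


# ---------------------------------------------------------------------------
# amplitude comodulogram
# ---------------------------------------------------------------------------

def stft_frame_magnitudes(epochs: np.ndarray, fs: float,
                          frame_s: float = 0.1, overlap: float = 0.5,
                          fmin: float = 0.5, fmax: float = 200.0):
    """Per-frame STFT magnitudes on a 0.5 Hz grid (Hamming, zero-padded).

    Frames of ``frame_s`` with the given overlap are taken inside each epoch
    and pooled; the FFT is zero-padded to length 2*fs so bins fall every
    0.5 Hz despite the 10 Hz native resolution of a 100 ms frame.
    """
    x = np.atleast_2d(np.asarray(epochs, dtype=float))
    if fs < 400:
        raise ValueError("comodulogram range 0.5-200 Hz needs fs >= 400 Hz")
    nper = int(round(frame_s * fs))
    hop = max(1, int(round(nper * (1 - overlap))))
    nfft = int(round(2 * fs))
    win = sps.get_window("hamming", nper)
    frames = np.lib.stride_tricks.sliding_window_view(x, nper, axis=-1)[:, ::hop]
    # float32 halves the FFT cost; magnitudes feed correlations only
    frames = (frames.reshape(-1, nper) * win).astype(np.float32)
    mags = np.abs(np.fft.rfft(frames, n=nfft, axis=-1))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    return freqs[sel], mags[:, sel]


def amplitude_comodulogram(epochs: np.ndarray, fs: float,
                           fmin: float = 0.5, fmax: float = 200.0) -> SpectralEstimate:
    """Pearson correlation matrix between frame-magnitude series of all bins."""
    freqs, mags = stft_frame_magnitudes(epochs, fs, fmin=fmin, fmax=fmax)
    if mags.shape[0] < 10:
        raise ValueError("comodulogram needs at least 10 STFT frames")
    z = mags - mags.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    z /= sd
    corr = (z.T @ z) / mags.shape[0]
    np.fill_diagonal(corr, 1.0)
    return SpectralEstimate(freqs=freqs, values=corr, kind="comodulogram",
                            meta={"fs": fs, "n_frames": mags.shape[0]})


def theta_gamma_correlation(comod: SpectralEstimate,
                            band1=FREQ_BANDS["theta"],
                            band2=FREQ_BANDS["high_gamma"]) -> float:
    """Mean comodulogram value over the theta x high-gamma block."""
    f = comod.freqs
    s1 = (f >= band1[0]) & (f <= band1[1])
    s2 = (f >= band2[0]) & (f <= band2[1])
    return float(comod.values[np.ix_(s1, s2)].mean())


# ---------------------------------------------------------------------------
# coherence entropy
# ---------------------------------------------------------------------------

def coherence_entropy(state_coherences) -> float:
    """Entropy (nats) of the normalized per-state mean theta coherences.

    Quantifies how homogeneous the average theta coherence is across the
    REM/QWK/ACT states: equal values give ln(3), a single dominant state
    drives the entropy toward 0. Invariant to common positive rescaling.
    """
    c = np.asarray(list(state_coherences.values())
                   if isinstance(state_coherences, dict) else state_coherences,
                   dtype=float)
    if np.any(c < 0):
        raise ValueError("coherence values must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("at least one coherence value must be positive")
    p = c / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
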