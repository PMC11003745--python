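"""Spectral parametrization: split a PSD into aperiodic (1/f) and periodic
(Gaussian peak) components, in the style of the FOOOF/specparam model.

The model in log10-power space over a fitting range (default 3-40 Hz) is

    log10 P(f) = b - chi * log10(f) + sum_k h_k * exp(-(f - c_k)^2 / (2 w_k^2))

with "fixed" (knee-free) aperiodic mode, at most four peaks, and a minimum
peak height of 0.05 log10 units. The fit alternates a robust aperiodic fit
(peaks masked by their positive residuals) with iterative Gaussian extraction
on the flattened spectrum, followed by a joint refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class Peak:
    center_hz: float
    height: float       # log10 power above the aperiodic component
    bandwidth_hz: float  # gaussian sd


@dataclass
class AperiodicFit:
    offset: float        # log10 power at 1 Hz
    exponent: float
    peaks: list[Peak] = field(default_factory=list)
    rmse: float = np.nan

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component in log10 power."""
        return self.offset - self.exponent * np.log10(freqs)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        out = self.aperiodic(freqs)
        for p in self.peaks:
            out = out + p.height * np.exp(
                -0.5 * ((freqs - p.center_hz) / p.bandwidth_hz) ** 2)
        return out


def _fit_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([np.ones_like(logf), -logf])
    coef, *_ = np.linalg.lstsq(A, logp, rcond=None)
    return float(coef[0]), float(coef[1])


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Aperiodic fit that ignores peak regions (positive-residual masking)."""
    b, chi = _fit_aperiodic(logf, logp)
    for _ in range(2):
        resid = logp - (b - chi * logf)
        # peaks only push residuals up: refit on the points at or below the
        # current aperiodic estimate (plus a small slack for noise)
        keep = resid <= np.percentile(np.clip(resid, 0, None), 2.5) + 1e-12
        if keep.sum() < 5:
            break
        b, chi = _fit_aperiodic(logf[keep], logp[keep])
    return b, chi


def _extract_peaks(f, flat, max_peaks, min_peak_height, peak_width_limits,
                   f_range) -> list[Peak]:
    """Iterative tallest-first Gaussian guesses, then a joint refinement."""
    wmin, wmax = peak_width_limits
    guesses: list[tuple[float, float, float]] = []
    resid = flat.copy()
    for _ in range(max_peaks):
        k = int(np.argmax(resid))
        h = resid[k]
        if h < min_peak_height:
            break
        half = h / 2.0
        left = k
        while left > 0 and resid[left] > half:
            left -= 1
        right = k
        while right < len(resid) - 1 and resid[right] > half:
            right += 1
        fwhm = max(f[right] - f[left], f[1] - f[0])
        w = float(np.clip(fwhm / 2.355, wmin, wmax))
        guesses.append((float(f[k]), float(h), w))
        resid = resid - h * np.exp(-0.5 * ((f - f[k]) / w) ** 2)

    if not guesses:
        return []
    p0, lo, hi = [], [], []
    for c, h, w in guesses:
        p0 += [c, h, w]
        lo += [f_range[0], 0.0, wmin]
        hi += [f_range[1], 3 * max(h, min_peak_height), wmax]
    try:
        popt, _ = curve_fit(_gaussian_sum, f, flat, p0=p0,
                            bounds=(lo, hi), maxfev=4000)
    except RuntimeError:
        popt = np.asarray(p0)
    return [Peak(float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
            for i in range(0, len(popt), 3)
            if popt[i + 1] >= min_peak_height]


def _gaussian_sum(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        c, h, w = params[i:i + 3]
        out = out + h * np.exp(-0.5 * ((f - c) / w) ** 2)
    return out


def parametrize_spectrum(freqs: np.ndarray, psd: np.ndarray,
                         f_range: tuple[float, float] = (3.0, 40.0),
                         max_peaks: int = 4,
                         min_peak_height: float = 0.05,
                         peak_width_limits: tuple[float, float] = (0.5, 12.0),
                         ) -> AperiodicFit:
    """Fit offset, exponent, and up to ``max_peaks`` Gaussian peaks to a PSD."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    df = np.median(np.diff(freqs))
    if freqs.min() > f_range[0] + df or freqs.max() < f_range[1] - df:
        raise ValueError(f"frequency grid does not cover {f_range} Hz")
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    if sel.sum() < 8:
        raise ValueError(f"fewer than 8 frequency bins inside {f_range} Hz")
    f = freqs[sel]
    p = psd[sel]
    if np.any(p <= 0):
        raise ValueError("PSD values must be positive for log fitting")
    logf = np.log10(f)
    logp = np.log10(p)

    b, chi = _robust_aperiodic(logf, logp)

    # alternate peak extraction and aperiodic refits: the first aperiodic
    # estimate is biased by the peaks it could not mask, which tilts the
    # flattened spectrum; a few rounds of extract-subtract-refit converge.
    peaks: list[Peak] = []
    for _ in range(4):
        flat = logp - (b - chi * logf)
        peaks = _extract_peaks(f, flat, max_peaks, min_peak_height,
                               peak_width_limits, f_range)
        peak_model = np.zeros_like(f)
        for pk in peaks:
            peak_model += pk.height * np.exp(
                -0.5 * ((f - pk.center_hz) / pk.bandwidth_hz) ** 2)
        b_new, chi_new = _fit_aperiodic(logf, logp - peak_model)
        converged = abs(chi_new - chi) < 1e-3 and abs(b_new - b) < 1e-3
        b, chi = b_new, chi_new
        if converged:
            break

    fit = AperiodicFit(offset=b, exponent=chi,
                       peaks=sorted(peaks, key=lambda q: -q.height))
    fit.rmse = float(np.sqrt(np.mean((logp - fit.model(f)) ** 2)))
    return fit


def oscillatory_band_power(fit: AperiodicFit, band: tuple[float, float],
                           mode: str = "height") -> float:
    """Summed peak height (or gaussian area) for peaks centered in ``band``."""
    lo, hi = band
    total = 0.0
    for p in fit.peaks:
        if lo <= p.center_hz <= hi:
            if mode == "height":
                total += p.height
            elif mode == "area":
                total += p.height * p.bandwidth_hz * np.sqrt(2 * np.pi)
            else:
                raise ValueError("mode must be 'height' or 'area'")
    return float(total)
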