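"""Two-dimensional spectral state maps.

Each epoch is embedded by two power ratios — ratio 1 = 4.5-9 / 4.5-50 Hz and
ratio 2 = 2-20 / 2-50 Hz — computed per region, reduced across the two
regions to their first principal component (one SVD per ratio), and smoothed
along time with a unit-sum 10-epoch Hann kernel. The map separates
wake / NREM / REM clusters; epochs moving faster than a fixed trajectory-speed
threshold (0.1 map units) are flagged as intermediate states (IS). A
3-component Gaussian mixture cross-validates the clusters against the
hypnogram, and the REM-ACT dissimilarity is the mean pairwise Euclidean
distance between epochs of the two states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency
from sklearn.mixture import GaussianMixture

from .bands import RATIO1_BANDS, RATIO2_BANDS
from .spectral import SpectralEstimate

IS_SPEED_THRESHOLD = 0.1


def spectral_ratios(psd: SpectralEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch (ratio1, ratio2) from a PSD estimate of one region."""
    f = psd.freqs
    if f[0] > 2.0 or f[-1] < 50.0:
        raise ValueError("PSD grid must cover 2-50 Hz")

    def ratio(bands):
        (nlo, nhi), (dlo, dhi) = bands
        num = psd.values[..., (f >= nlo) & (f <= nhi)].sum(axis=-1)
        den = psd.values[..., (f >= dlo) & (f <= dhi)].sum(axis=-1)
        if np.any(den <= 0):
            raise ValueError("zero denominator band power")
        return num / den

    return ratio(RATIO1_BANDS), ratio(RATIO2_BANDS)


@dataclass
class StateMap:
    coords: np.ndarray                # (n_epochs, 2) smoothed scores
    speeds: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n_epochs(self) -> int:
        return len(self.coords)


def _first_pc_score(hpc: np.ndarray, pfc: np.ndarray,
                    standardize: bool = True) -> np.ndarray:
    """First-singular-vector score of the two-region series, sign-fixed.

    Each region's series is z-scored (or centered only), the 2-column matrix
    is reduced by SVD, and the sign is fixed so the score correlates
    positively with the HPC series.
    """
    cols = []
    for x in (hpc, pfc):
        x = np.asarray(x, dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError("constant ratio series (zero variance)")
        cols.append((x - x.mean()) / (sd if standardize else 1.0))
    X = np.column_stack(cols)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    score = u[:, 0] * s[0]
    if np.corrcoef(score, cols[0])[0, 1] < 0:
        score = -score
    return score


def hann_smooth(x: np.ndarray, length: int = 10) -> np.ndarray:
    """Convolution with a unit-sum Hann kernel, reflect-padded."""
    kernel = windows.hann(length)
    kernel = kernel / kernel.sum()
    pad = len(kernel) // 2
    xp = np.pad(x, pad, mode="reflect")
    sm = np.convolve(xp, kernel, mode="same")
    return sm[pad:pad + len(x)]


def build_state_map(hpc_ratios: tuple[np.ndarray, np.ndarray],
                    pfc_ratios: tuple[np.ndarray, np.ndarray],
                    smooth_epochs: int = 10,
                    standardize: bool = False) -> StateMap:
    """State-map coordinates from the per-region (ratio1, ratio2) series.

    By default the region series are centered but not variance-scaled, so the
    coordinates stay in power-ratio units — the scale on which the fixed IS
    speed threshold (0.1) is defined. ``standardize=True`` z-scores the
    regions before the SVD instead.
    """
    n = len(hpc_ratios[0])
    if n < 20:
        raise ValueError("state map needs at least 20 epochs")
    coords = np.column_stack([
        hann_smooth(_first_pc_score(hpc_ratios[k], pfc_ratios[k], standardize),
                    smooth_epochs)
        for k in (0, 1)
    ])
    m = StateMap(coords=coords)
    m.speeds = trajectory_speed(m)
    m.is_flags = flag_intermediate(m)
    return m


def trajectory_speed(m: StateMap) -> np.ndarray:
    """Euclidean distance from each epoch to its predecessor (first = NaN)."""
    d = np.linalg.norm(np.diff(m.coords, axis=0), axis=1)
    return np.concatenate([[np.nan], d])


def flag_intermediate(m: StateMap,
                      threshold: float = IS_SPEED_THRESHOLD) -> np.ndarray:
    """IS flags: epochs whose trajectory speed exceeds the threshold."""
    speeds = m.speeds if m.speeds.size else trajectory_speed(m)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(speeds, nan=0.0) > threshold


@dataclass
class ClusterValidation:
    cluster: np.ndarray        # assigned component (-1 = below posterior cut)
    posterior: np.ndarray      # max posterior per epoch
    chi2: float
    p_value: float
    purity: float
    low_correspondence: bool
    contingency: np.ndarray


def validate_clusters(m: StateMap, labels: np.ndarray, seed: int = 0,
                      posterior_threshold: float = 0.8,
                      min_assigned: int = 30) -> ClusterValidation:
    """3-component GMM on the map, validated against {NREM, REM, awake}.

    Epochs with maximum posterior below the threshold stay unassigned. The
    correspondence is summarized by the chi-squared statistic of the assigned
    cluster x coarse-state contingency and by cluster purity (majority-state
    fraction). Low correspondence raises a QC flag only — no exclusion.
    """
    labels = np.asarray(labels).astype(str)
    coarse = np.where(np.isin(labels, ["ACT", "QWK"]), "awake", labels)
    gmm = GaussianMixture(n_components=3, covariance_type="full",
                          random_state=seed, n_init=3)
    gmm.fit(m.coords)
    post = gmm.predict_proba(m.coords)
    maxp = post.max(axis=1)
    cluster = np.where(maxp >= posterior_threshold, post.argmax(axis=1), -1)
    assigned = cluster >= 0
    if assigned.sum() < min_assigned:
        raise ValueError(
            f"only {assigned.sum()} epochs pass the posterior threshold "
            f"(need >= {min_assigned})")
    states = ["awake", "NREM", "REM"]
    table = np.zeros((3, 3))
    for k in range(3):
        for j, s in enumerate(states):
            table[k, j] = np.sum((cluster == k) & (coarse == s))
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    sub = table[np.ix_(keep_rows, keep_cols)]
    if sub.shape[0] > 1 and sub.shape[1] > 1:
        chi2, p, *_ = chi2_contingency(sub)
    else:
        chi2, p = 0.0, 1.0
    purity = float(table.max(axis=1).sum() / table.sum()) if table.sum() else 0.0
    return ClusterValidation(
        cluster=cluster, posterior=maxp, chi2=float(chi2), p_value=float(p),
        purity=purity, low_correspondence=bool(p > 1e-3 or purity < 0.5),
        contingency=table,
    )


def rem_act_distance(m: StateMap, labels: np.ndarray,
                     exclude_is: bool = True,
                     max_pairs: int = 1_000_000, seed: int = 0) -> dict:
    """Mean pairwise Euclidean distance between REM and ACT epochs."""
    labels = np.asarray(labels).astype(str)
    keep = ~m.is_flags if (exclude_is and m.is_flags.size) else np.ones(
        len(labels), dtype=bool)
    rem = m.coords[(labels == "REM") & keep]
    act = m.coords[(labels == "ACT") & keep]
    for name, pts in (("REM", rem), ("ACT", act)):
        if len(pts) == 0:
            raise ValueError(f"no {name} epochs available for the distance")
    n_pairs = len(rem) * len(act)
    subsampled = n_pairs > max_pairs
    if subsampled:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, len(rem), max_pairs)
        jj = rng.integers(0, len(act), max_pairs)
        d = np.linalg.norm(rem[ii] - act[jj], axis=1)
    else:
        d = cdist(rem, act).ravel()
    return {
        "mean_distance": float(d.mean()),
        "sd_distance": float(d.std()),
        "n_pairs": int(n_pairs),
        "subsampled": subsampled,
        "se_mean": float(d.std() / np.sqrt(len(d))),
    }
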