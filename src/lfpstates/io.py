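"""Recording container, file I/O, epoching, and zero-phase filtering.

A :class:`Recording` holds the three continuous channels every stage of the
pipeline consumes: prefrontal (PFC) and hippocampal (HPC) local field
potentials plus one EMG channel, all at a common sampling rate. Time is
measured in seconds from recording start; epochs are half-open intervals
``[t, t + length)`` so that event-epoch intersection is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

CHANNEL_ROLES = ("pfc", "hpc", "emg")


@dataclass
class Recording:
    """Three-channel continuous recording (PFC, HPC LFPs + EMG)."""

    pfc: np.ndarray
    hpc: np.ndarray
    emg: np.ndarray
    fs: float
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.pfc = np.asarray(self.pfc, dtype=np.float64)
        self.hpc = np.asarray(self.hpc, dtype=np.float64)
        self.emg = np.asarray(self.emg, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.pfc)
        for role in CHANNEL_ROLES:
            x = getattr(self, role)
            if x.ndim != 1:
                raise ValueError(f"channel {role} must be 1-D")
            if len(x) != n:
                raise ValueError(
                    f"channel lengths differ: pfc has {n}, {role} has {len(x)}"
                )
            if np.isnan(x).any():
                raise ValueError(f"channel {role} contains NaN")

    @property
    def n_samples(self) -> int:
        return len(self.pfc)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        if role.lower() not in CHANNEL_ROLES:
            raise KeyError(f"channel role {role!r} not found; have {CHANNEL_ROLES}")
        return getattr(self, role.lower())


@dataclass
class EpochGrid:
    """Non-overlapping (or Welch-style overlapping) epoch grid in seconds."""

    length_s: float
    starts_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_epochs(self) -> int:
        return len(self.starts_s)

    def index_at(self, t: float) -> int:
        """Index of the epoch whose half-open interval contains time ``t``."""
        idx = np.searchsorted(self.starts_s, t, side="right") - 1
        if idx < 0 or t >= self.starts_s[idx] + self.length_s:
            raise ValueError(f"time {t} s falls outside the epoch grid")
        return int(idx)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def save_recording(path, rec: Recording) -> None:
    """Write a Recording as HDF5 (datasets /pfc /hpc /emg; attrs fs, subject, group)."""
    with h5py.File(path, "w") as f:
        for role in CHANNEL_ROLES:
            f.create_dataset(role, data=getattr(rec, role).astype(np.float32))
        f.attrs["fs"] = rec.fs
        f.attrs["subject"] = rec.subject
        f.attrs["group"] = rec.group


def load_recording(path, format: str | None = None) -> Recording:
    """Load a Recording from HDF5, NPZ, or (read-only) EDF.

    Format is inferred from the file extension when not given. Channel roles
    PFC/HPC/EMG must all be present (case-insensitive match for EDF channel
    names); a missing role raises an explicit error naming it.
    """
    path = str(path)
    if format is None:
        low = path.lower()
        if low.endswith((".h5", ".hdf5")):
            format = "hdf5"
        elif low.endswith(".npz"):
            format = "npz"
        elif low.endswith(".edf"):
            format = "edf"
        else:
            raise ValueError(f"cannot infer format from {path!r}")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            chans = {}
            for role in CHANNEL_ROLES:
                if role not in f:
                    raise KeyError(f"channel role {role.upper()} not found in {path}")
                chans[role] = np.asarray(f[role], dtype=np.float64)
            return Recording(
                fs=float(f.attrs["fs"]),
                subject=str(f.attrs.get("subject", "")),
                group=str(f.attrs.get("group", "")),
                **chans,
            )
    if format == "npz":
        data = np.load(path)
        for role in CHANNEL_ROLES:
            if role not in data:
                raise KeyError(f"channel role {role.upper()} not found in {path}")
        return Recording(
            pfc=data["pfc"], hpc=data["hpc"], emg=data["emg"],
            fs=float(data["fs"]),
            subject=str(data["subject"]) if "subject" in data else "",
            group=str(data["group"]) if "group" in data else "",
        )
    if format == "edf":
        import mne  # optional heavyweight import, EDF read only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        name_map = {name.lower(): name for name in raw.ch_names}
        chans = {}
        for role in CHANNEL_ROLES:
            if role not in name_map:
                raise KeyError(f"channel role {role.upper()} not found in {path}")
            chans[role] = raw.get_data(picks=[name_map[role]])[0]
        return Recording(fs=float(raw.info["sfreq"]), **chans)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epochize(n_samples: int, fs: float, length_s: float,
             overlap_fraction: float = 0.0) -> EpochGrid:
    """Build an epoch grid over a signal of ``n_samples`` at rate ``fs``.

    With zero overlap this tiles the recording with ``floor(duration/length)``
    half-open epochs, dropping any partial tail. With overlap f the hop is
    ``length * (1 - f)`` (Welch-style internal grids).
    """
    if length_s <= 0:
        raise ValueError("epoch length must be positive")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    duration = n_samples / fs
    if length_s > duration:
        raise ValueError(f"epoch length {length_s} s exceeds duration {duration} s")
    hop = length_s * (1.0 - overlap_fraction)
    n = int(np.floor((duration - length_s) / hop)) + 1
    starts = np.arange(n) * hop
    return EpochGrid(length_s=length_s, starts_s=starts)


def epoch_views(x: np.ndarray, fs: float, grid: EpochGrid) -> np.ndarray:
    """Stack per-epoch signal segments as a 2-D array (n_epochs, n_per_epoch)."""
    n_per = int(round(grid.length_s * fs))
    starts = np.round(grid.starts_s * fs).astype(int)
    return np.stack([x[s:s + n_per] for s in starts])


def subdivide(grid: EpochGrid, sub_length_s: float) -> EpochGrid:
    """Split each epoch into contiguous sub-epochs (e.g. 30 s -> ten 3 s)."""
    k = grid.length_s / sub_length_s
    if abs(k - round(k)) > 1e-9:
        raise ValueError("epoch length must be an integer multiple of sub-length")
    k = int(round(k))
    starts = (grid.starts_s[:, None] + np.arange(k) * sub_length_s).ravel()
    return EpochGrid(length_s=sub_length_s, starts_s=starts)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _butter_sos(cutoff_hz, fs: float, btype: str, order: int = 4):
    nyq = fs / 2.0
    crit = np.atleast_1d(np.asarray(cutoff_hz, dtype=float))
    if np.any(crit >= nyq):
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({nyq} Hz)")
    if np.any(crit <= 0):
        raise ValueError("cutoff must be positive")
    wn = crit / nyq
    return signal.butter(order, wn if wn.size > 1 else float(wn[0]),
                         btype=btype, output="sos")


def zero_phase_lowpass(x: np.ndarray, fs: float, cutoff_hz: float,
                       order: int = 4) -> np.ndarray:
    """Forward-backward 4th-order Butterworth low-pass (zero phase lag)."""
    sos = _butter_sos(cutoff_hz, fs, "lowpass", order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def zero_phase_highpass(x: np.ndarray, fs: float, cutoff_hz: float,
                        order: int = 4) -> np.ndarray:
    sos = _butter_sos(cutoff_hz, fs, "highpass", order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def zero_phase_bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
                        order: int = 4) -> np.ndarray:
    sos = _butter_sos([low_hz, high_hz], fs, "bandpass", order)
    return signal.sosfiltfilt(sos, x, axis=-1)
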