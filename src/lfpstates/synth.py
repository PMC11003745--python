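"""Ground-truthed synthetic LFP cohort generator.

Emulates freely-moving dual-site recordings (PFC + HPC LFP, one EMG channel)
whose statistics drive every downstream stage: a four-state Markov sleep-wake
architecture (ACT/QWK/NREM/REM) on a 5 s grid; per-state 1/f^chi background
plus narrow-band oscillators (filtered noise, not sinusoids); an HPC->PFC
theta channel built as a lagged, scaled copy of the HPC theta component plus
independent noise so that band coherence hits a planted target; PFC high-gamma
whose amplitude envelope is correlated with the theta envelope at a planted
Pearson r; state-dependent EMG variance; and optional additive spike-wave
discharges (SWDs) with a 7.5 Hz harmonic-stack morphology.

Every planted quantity is recorded in :class:`GroundTruth` so that recovery by
the downstream estimators closes the loop in tests.

Note on the coupling target: the amplitude comodulogram correlates per-frame
STFT magnitudes, and for Gaussian carriers each 0.5 Hz bin magnitude carries
irreducible Rayleigh fluctuation that attenuates any envelope correlation.
The planted ``coupling_r`` is therefore defined as the target of the
*measured* theta/high-gamma block correlation; the generator boosts the
internal envelope correlation by an analytically derived measurement-chain
factor (see ``_coupling_boost``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .bands import FREQ_BANDS, STATES
from .io import Recording

THETA_BAND = FREQ_BANDS["theta"]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class Oscillator:
    """Narrow-band filtered-noise component: Gaussian spectral profile."""

    center_hz: float
    bandwidth_hz: float  # full width at half maximum of the spectral profile
    amplitude: float     # standard deviation of the component, signal units

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("oscillator amplitude must be >= 0")
        if self.center_hz <= 0 or self.bandwidth_hz <= 0:
            raise ValueError("oscillator center/bandwidth must be positive")


@dataclass
class StateParams:
    """Generative parameters of one sleep-wake state."""

    label: str
    exponent: dict[str, float]            # region -> aperiodic exponent chi
    offset: dict[str, float]              # region -> log10 background amplitude
    theta_amp: dict[str, float]           # region -> theta component std
    oscillators: dict[str, list[Oscillator]]  # non-theta oscillators per region
    theta_coherence: float = 0.3          # target band-mean MSC, HPC-PFC theta
    lag_ms: float = 40.0                  # HPC leads PFC by this lag
    coupling_r: float = 0.3               # target theta->high-gamma magnitude r
    emg_var: float = 1.0                  # EMG signal variance
    dwell_s: float = 100.0                # mean dwell time
    theta_center_hz: float = 7.75
    theta_bw_hz: float = 6.5

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ValueError(f"unknown state label {self.label!r}")
        for region, chi in self.exponent.items():
            if chi < 0:
                raise ValueError(f"exponent for {region} must be >= 0")
        for region, amp in self.theta_amp.items():
            if amp < 0:
                raise ValueError(f"theta amplitude for {region} must be >= 0")
        if not 0 < self.lag_ms <= 200:
            raise ValueError("lag must be within (0, 200] ms")
        if not -1 <= self.coupling_r <= 1:
            raise ValueError("coupling r must be in [-1, 1]")
        if not 0 <= self.theta_coherence < 1:
            raise ValueError("theta coherence target must be in [0, 1)")
        if self.dwell_s <= 0:
            raise ValueError("dwell time must be positive")
        if self.emg_var < 0:
            raise ValueError("EMG variance must be >= 0")


@dataclass
class SWDSpec:
    """Spike-wave discharge event model."""

    subject_prob: float = 0.0             # P(subject expresses SWDs at all)
    rate_per_min: dict[str, float] = field(default_factory=dict)  # per state
    duration_mean_s: float = 6.614        # mean ictal duration
    duration_sd_s: float = 0.283          # SD implied by a 4.281% CV
    fundamental_hz: float = 7.5
    amplitude_factor: float = 5.0         # event RMS relative to local RMS

    def __post_init__(self) -> None:
        if not 0 <= self.subject_prob <= 1:
            raise ValueError("SWD subject probability must be in [0, 1]")
        if self.duration_mean_s <= 0:
            raise ValueError("SWD duration mean must be positive")
        if any(r < 0 for r in self.rate_per_min.values()):
            raise ValueError("SWD rates must be >= 0")


@dataclass
class CohortSpec:
    """Full per-subject generative specification."""

    group: str                            # "CTRL" | "ELS"
    states: dict[str, StateParams]
    transition: np.ndarray                # 4x4 row-stochastic, STATES order
    swd: SWDSpec = field(default_factory=SWDSpec)
    fs: float = 500.0
    duration_s: float = 1800.0
    seed: int = 0
    # ELS "REM-like ACT": probability that a 30 s ACT block draws its spectral
    # recipe blended toward REM parameters (EMG stays awake-like).
    act_rem_blend_prob: float = 0.0
    act_rem_blend_weight: float = 1.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.fs < 500:
            raise ValueError("sampling rate must be >= 500 Hz")
        validate_transition(self.transition)
        missing = [s for s in STATES if s not in self.states]
        if missing:
            raise ValueError(f"missing StateParams for {missing}")


def validate_transition(P: np.ndarray) -> None:
    if P.shape != (len(STATES), len(STATES)):
        raise ValueError(f"transition matrix must be {len(STATES)}x{len(STATES)}")
    for i, row in enumerate(P):
        if np.any(row < 0) or not np.isclose(row.sum(), 1.0, atol=1e-8):
            raise ValueError(
                f"transition row {i} ({STATES[i]}) is not a probability "
                f"distribution: {row}"
            )


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic Recording."""

    states_5s: np.ndarray                 # per 5 s epoch state label
    swd_intervals: list[tuple[float, float]] = field(default_factory=list)
    planted: dict = field(default_factory=dict)  # per-state planted parameters

    def states_30s(self) -> np.ndarray:
        """Modal ground-truth label on the 30 s grid (groups of six epochs)."""
        n = len(self.states_5s) // 6
        out = []
        for i in range(n):
            grp = self.states_5s[6 * i:6 * i + 6]
            labels, counts = np.unique(grp, return_counts=True)
            out.append(labels[np.argmax(counts)])
        return np.asarray(out)


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

EPOCH_S = 5.0


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_state_sequence(spec: CohortSpec, seed: int,
                          require_all_states: bool = False,
                          max_tries: int = 200) -> np.ndarray:
    """Sample the per-5 s-epoch state label sequence from the Markov chain.

    The initial state is drawn from the stationary distribution. With
    ``require_all_states`` the draw is repeated (deterministically, from the
    same seeded stream) until every state also survives modal consolidation
    onto the 30 s grid (at least three modal 30 s epochs each) — used for
    cohort subjects, where downstream per-state estimates need all states.
    """
    validate_transition(spec.transition)
    if spec.duration_s < 30:
        raise ValueError("duration must be >= 30 s")
    n_ep = int(np.floor(spec.duration_s / EPOCH_S))
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(spec.transition)
    cum = np.cumsum(spec.transition, axis=1)
    for _ in range(max_tries):
        seq = np.empty(n_ep, dtype=int)
        seq[0] = rng.choice(len(STATES), p=pi)
        u = rng.random(n_ep - 1)
        for t in range(1, n_ep):
            seq[t] = np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right")
        labels = np.asarray([STATES[i] for i in seq])
        if not require_all_states:
            return labels
        modal = GroundTruth(states_5s=labels).states_30s()
        counts = {s: int(np.sum(modal == s)) for s in STATES}
        if all(c >= 3 for c in counts.values()):
            return labels
    raise RuntimeError(
        f"could not draw a sequence containing all states in {max_tries} tries; "
        "increase duration or adjust the transition matrix"
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Contiguous runs as (start_epoch, n_epochs, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i - start, str(labels[start])))
            start = i
    return out


# ---------------------------------------------------------------------------
# component synthesis helpers
# ---------------------------------------------------------------------------

def _shaped_noise(rng, n, fs, profile_fn):
    """Gaussian noise with the given one-sided spectral amplitude profile."""
    m = next_fast_len(n)
    f = np.fft.rfftfreq(m, 1.0 / fs)
    prof = profile_fn(f)
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(m)) * prof, m)[:n]
    sd = x.std()
    return (x / sd if sd > 0 else x), f, prof


def _colored_noise(rng, n, fs, exponent, knee_hz=0.5):
    """1/f^exponent Gaussian noise, unit variance (flat below ``knee_hz``)."""

    def prof_fn(f):
        prof = np.maximum(f, knee_hz) ** (-exponent / 2.0)
        prof[0] = 0.0
        return prof

    return _shaped_noise(rng, n, fs, prof_fn)


def _band_noise(rng, n, fs, center_hz, bw_hz, order: int = 2):
    """Unit-variance narrow-band Gaussian noise.

    ``order=2`` gives a Gaussian spectral profile (FWHM = bw); higher even
    orders give a flat-top ("supergaussian") profile of half-width bw/2 used
    for the theta component so that coherence is uniform across the band.
    """
    if order == 2:
        sigma = bw_hz / 2.355  # FWHM -> spectral sd
    else:
        sigma = bw_hz / 2.0

    def prof_fn(f):
        prof = np.exp(-0.5 * np.abs((f - center_hz) / sigma) ** order)
        prof[f < 0.1] = 0.0
        return prof

    return _shaped_noise(rng, n, fs, prof_fn)[0]


def _slow_lognormal(rng, n, fs, cv, cutoff_hz=0.7):
    """Positive slowly varying envelope with E=1 and the requested CV."""
    if cv <= 0:
        return np.ones(n)
    z = _smooth_noise(rng, n, fs, cutoff_hz)
    s2 = np.log1p(cv * cv)
    return np.exp(np.sqrt(s2) * z - s2 / 2.0)


def _smooth_noise(rng, n, fs, cutoff_hz):
    """Low-passed standardized Gaussian noise (Gaussian spectral roll-off)."""

    def prof_fn(f):
        prof = np.exp(-0.5 * (f / cutoff_hz) ** 2)
        prof[0] = 0.0
        return prof

    return _shaped_noise(rng, n, fs, prof_fn)[0]


def _band_power_fraction(f, prof, lo, hi):
    """Fraction of component variance falling inside [lo, hi] Hz."""
    p2 = prof ** 2
    tot = p2.sum()
    if tot == 0:
        return 0.0
    sel = (f >= lo) & (f <= hi)
    return float(p2[sel].sum() / tot)


_RAYLEIGH_REL_VAR = 4.0 / np.pi - 1.0  # variance/mean^2 of a Rayleigh variate


def _rayleigh_attenuation(env_cv: float) -> float:
    """corr(m*R, m) for envelope m (CV given) times independent Rayleigh R."""
    s2 = env_cv * env_cv
    return float(np.sqrt(s2 / ((1.0 + _RAYLEIGH_REL_VAR) * s2 + _RAYLEIGH_REL_VAR)))


#: empirical attenuation of the theta-side magnitude readout relative to the
#: analytic envelope (windowing + background leakage); validated by the
#: planted-coupling recovery tests.
_THETA_READOUT_ATTEN = 0.65


def _coupling_boost(r_target: float, gamma_env_cv: float) -> float:
    """Envelope correlation needed so the measured block r hits ``r_target``."""
    a_gamma = _rayleigh_attenuation(gamma_env_cv)
    c = r_target / (a_gamma * _THETA_READOUT_ATTEN)
    return float(np.clip(c, -0.99, 0.99))


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

_GAMMA_ENV_CV = 1.0  # CV of the lognormal high-gamma envelope
_THETA_ENV_CV = 0.8  # CV of the slow theta amplitude modulation


def synthesize_recording(spec: CohortSpec, states: np.ndarray,
                         seed: int) -> tuple[Recording, GroundTruth]:
    """Render the three channels for a given state sequence.

    Each contiguous same-state run is synthesized independently (the runs are
    concatenated without crossfading; the 5 s grid guarantees no epoch
    straddles a boundary). ELS-style "REM-like ACT" blocks are drawn here when
    ``spec.act_rem_blend_prob > 0``.
    """
    states = np.asarray(states)
    fs = spec.fs
    spe = int(round(EPOCH_S * fs))
    max_lag = max(p.lag_ms for p in spec.states.values())
    if max_lag / 1000.0 > EPOCH_S:
        raise ValueError("HPC->PFC lag exceeds one epoch")
    rng = np.random.default_rng(seed)
    n_total = len(states) * spe
    chans = {r: np.empty(n_total) for r in ("pfc", "hpc", "emg")}

    pieces: list[tuple[int, int, StateParams]] = []  # (start_epoch, n_ep, params)
    for start, n_ep, label in _runs(states):
        params = spec.states[label]
        if label == "ACT" and spec.act_rem_blend_prob > 0:
            # subdivide ACT runs into 30 s blocks, each possibly REM-flavored
            pos = start
            remaining = n_ep
            while remaining > 0:
                blk = min(6, remaining)
                if rng.random() < spec.act_rem_blend_prob:
                    pieces.append((pos, blk, _blend_toward_rem(
                        params, spec.states["REM"], spec.act_rem_blend_weight)))
                else:
                    pieces.append((pos, blk, params))
                pos += blk
                remaining -= blk
        else:
            pieces.append((start, n_ep, params))

    for start, n_ep, params in pieces:
        n = n_ep * spe
        sl = slice(start * spe, start * spe + n)
        pfc, hpc, emg = _synthesize_piece(rng, n, fs, params)
        chans["pfc"][sl] = pfc
        chans["hpc"][sl] = hpc
        chans["emg"][sl] = emg

    rec = Recording(pfc=chans["pfc"], hpc=chans["hpc"], emg=chans["emg"],
                    fs=fs, group=spec.group)
    planted = {
        label: {
            "exponent": dict(p.exponent),
            "theta_coherence": p.theta_coherence,
            "lag_ms": p.lag_ms,
            "coupling_r": p.coupling_r,
            "theta_amp": dict(p.theta_amp),
            "emg_var": p.emg_var,
        }
        for label, p in spec.states.items()
    }
    truth = GroundTruth(states_5s=states.copy(), planted=planted)
    return rec, truth


def _blend_toward_rem(act: StateParams, rem: StateParams,
                      w: float) -> StateParams:
    """Spectral recipe pulled toward REM; EMG and dwell stay awake-like."""
    mix = lambda a, b: (1 - w) * a + w * b
    return replace(
        act,
        exponent={r: mix(act.exponent[r], rem.exponent[r]) for r in act.exponent},
        theta_amp={r: mix(act.theta_amp[r], rem.theta_amp[r]) for r in act.theta_amp},
        oscillators={
            r: [Oscillator(o.center_hz, o.bandwidth_hz,
                           mix(o.amplitude, ro.amplitude))
                for o, ro in zip(act.oscillators[r], rem.oscillators[r])]
            for r in act.oscillators
        },
        theta_coherence=mix(act.theta_coherence, rem.theta_coherence),
    )


def _synthesize_piece(rng, n, fs, p: StateParams):
    """Render one stationary same-state stretch of length n samples."""
    lo, hi = THETA_BAND
    lag_n = int(round(p.lag_ms / 1000.0 * fs))

    bg = {}
    bg_theta_power = {}
    for region in ("pfc", "hpc"):
        x, f, prof = _colored_noise(rng, n, fs, p.exponent[region])
        scale = 10.0 ** p.offset[region]
        bg[region] = x * scale
        bg_theta_power[region] = _band_power_fraction(f, prof, lo, hi) * scale ** 2

    # HPC theta: slow-envelope-modulated narrow-band noise
    u_h = _band_noise(rng, n, fs, p.theta_center_hz, p.theta_bw_hz, order=6)
    m_h = _slow_lognormal(rng, n, fs, _THETA_ENV_CV)
    theta_h = m_h * u_h
    sd = theta_h.std()
    theta_h = theta_h / sd * p.theta_amp["hpc"] if sd > 0 else theta_h

    # PFC theta: lagged scaled copy of the HPC theta plus independent noise;
    # the mixing ratio is solved so that band coherence (including the PFC
    # background power inside the band) hits the planted target.
    amp_p2 = p.theta_amp["pfc"] ** 2
    T = amp_p2 + bg_theta_power["pfc"]
    coupled_pow = min(p.theta_coherence * T, amp_p2)
    indep_pow = amp_p2 - coupled_pow
    coupled = np.roll(theta_h, lag_n)
    csd = coupled.std()
    coupled = coupled / csd * np.sqrt(coupled_pow) if csd > 0 else coupled
    u_i = _band_noise(rng, n, fs, p.theta_center_hz, p.theta_bw_hz, order=6)
    # the independent carrier shares the (lagged) HPC theta envelope: theta
    # power waxes and wanes jointly across the loop, which keeps the
    # coupled/independent power ratio - hence the coherence - stationary
    m_i = np.roll(m_h, lag_n)
    indep = m_i * u_i
    isd = indep.std()
    indep = indep / isd * np.sqrt(indep_pow) if isd > 0 else indep
    theta_p = coupled + indep

    out = {"pfc": bg["pfc"] + theta_p, "hpc": bg["hpc"] + theta_h}

    for region in ("pfc", "hpc"):
        for osc in p.oscillators.get(region, []):
            if osc.amplitude <= 0:
                continue
            u = _band_noise(rng, n, fs, osc.center_hz, osc.bandwidth_hz)
            in_high_gamma = (FREQ_BANDS["high_gamma"][0] <= osc.center_hz
                             <= FREQ_BANDS["high_gamma"][1])
            if region == "pfc" and in_high_gamma and abs(p.coupling_r) > 0:
                comp = _coupled_gamma(rng, n, fs, u, theta_p, p.coupling_r)
            else:
                comp = u
            csd2 = comp.std()
            out[region] = out[region] + comp / csd2 * osc.amplitude

    emg = rng.standard_normal(n) * np.sqrt(p.emg_var)
    return out["pfc"], out["hpc"], emg


def _coupled_gamma(rng, n, fs, carrier, theta_signal, r_target):
    """High-gamma with envelope correlated to the theta band magnitude.

    The theta envelope is tracked at the ~100 ms comodulogram frame scale
    (low-passed analytic magnitude) so that the gamma amplitude co-fluctuates
    with what the measurement actually reads out.
    """
    env = np.abs(sps.hilbert(theta_signal, N=next_fast_len(n))[:n])
    f = np.fft.rfftfreq(n, 1.0 / fs)
    prof = np.exp(-0.5 * (f / 4.0) ** 2)
    env_s = np.fft.irfft(np.fft.rfft(env) * prof, n)
    sd = env_s.std()
    z_e = (env_s - env_s.mean()) / sd if sd > 0 else np.zeros(n)
    w = _smooth_noise(rng, n, fs, 4.0)
    c = _coupling_boost(r_target, _GAMMA_ENV_CV)
    z_mix = c * z_e + np.sqrt(max(0.0, 1 - c * c)) * w
    s2 = np.log1p(_GAMMA_ENV_CV ** 2)
    # clip the lognormal tail: unbounded spikes splash carrier power far
    # outside the gamma band and contaminate the 3-40 Hz aperiodic fit
    m_g = np.clip(np.exp(np.sqrt(s2) * z_mix - s2 / 2.0), 0.0, 5.0)
    return m_g * carrier


# ---------------------------------------------------------------------------
# spike-wave discharges
# ---------------------------------------------------------------------------

def swd_waveform(duration_s: float, fs: float, fundamental_hz: float) -> np.ndarray:
    """Harmonic stack (f0, 2f0, 3f0) with cubic waveshaping, Tukey-tapered."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    y = (np.sin(2 * np.pi * fundamental_hz * t)
         + 0.5 * np.sin(2 * np.pi * 2 * fundamental_hz * t + 0.8)
         + 0.25 * np.sin(2 * np.pi * 3 * fundamental_hz * t + 1.6))
    y = y + 0.6 * y ** 3  # spike-like sharpening
    y *= sps.windows.tukey(n, alpha=0.15)
    sd = y.std()
    return y / sd if sd > 0 else y


def inject_swd(rec: Recording, truth: GroundTruth, spec: CohortSpec,
               seed: int) -> tuple[Recording, GroundTruth]:
    """Additively place SWD events by per-state rates; update the truth.

    Events are placed entirely inside same-state runs (so NREM-only rates can
    never produce events overlapping other states), never overlap each other,
    and never straddle the recording edges. The event waveform is scaled to
    ``amplitude_factor`` times the local PFC RMS and added to PFC, with a
    half-amplitude copy on HPC.
    """
    rng = np.random.default_rng(seed)
    swd = spec.swd
    fs = rec.fs
    pfc = rec.pfc.copy()
    hpc = rec.hpc.copy()
    events: list[tuple[float, float]] = []
    if any(r > 0 for r in swd.rate_per_min.values()):
        for start, n_ep, label in _runs(truth.states_5s):
            rate = swd.rate_per_min.get(label, 0.0)
            if rate <= 0:
                continue
            run_len_s = n_ep * EPOCH_S
            n_events = rng.poisson(rate * run_len_s / 60.0)
            run_start_s = start * EPOCH_S
            placed: list[tuple[float, float]] = []
            for _ in range(n_events):
                dur = float(np.clip(
                    rng.normal(swd.duration_mean_s, swd.duration_sd_s),
                    1.0, None))
                if dur >= run_len_s:
                    continue
                for _try in range(20):
                    onset = run_start_s + rng.uniform(0, run_len_s - dur)
                    if all(onset + dur <= s or onset >= e for s, e in placed):
                        placed.append((onset, onset + dur))
                        break
            for onset, offset in placed:
                i0 = int(round(onset * fs))
                wf = swd_waveform(offset - onset, fs, swd.fundamental_hz)
                i1 = i0 + len(wf)
                local_rms = np.sqrt(np.mean(pfc[i0:i1] ** 2))
                amp = swd.amplitude_factor * local_rms
                pfc[i0:i1] += amp * wf
                hpc[i0:i1] += 0.5 * amp * wf
            events.extend(placed)
    events.sort()
    out_rec = Recording(pfc=pfc, hpc=hpc, emg=rec.emg.copy(), fs=fs,
                        subject=rec.subject, group=rec.group)
    out_truth = GroundTruth(states_5s=truth.states_5s.copy(),
                            swd_intervals=sorted(truth.swd_intervals + events),
                            planted=copy.deepcopy(truth.planted))
    return out_rec, out_truth


# ---------------------------------------------------------------------------
# presets and cohorts
# ---------------------------------------------------------------------------

def _default_transition() -> np.ndarray:
    """Per-5 s-epoch transition matrix (rows ACT, QWK, NREM, REM)."""
    # flow-balanced for stationary occupancy ~(25, 15, 45, 15) %
    return np.array([
        [0.96, 0.04, 0.0, 0.0],                  # ACT: dwell ~125 s
        [0.025, 0.875, 0.10, 0.0],               # QWK: dwell ~40 s
        [0.0, 0.0055, 0.9667, 0.0278],           # NREM: dwell ~150 s
        [0.0417, 0.0416, 0.0, 0.9167],           # REM: dwell ~60 s
    ])


def _base_states(group: str) -> dict[str, StateParams]:
    els = group == "ELS"
    exp_pfc = 1.2 if els else 1.5
    exp_hpc = 1.4
    act_theta_hpc = 1.2 * (1.3 if els else 1.0)

    def oscs(low_gamma, pfc_gamma, hpc_gamma, delta_amp, delta_center=2.0,
             delta_bw=1.6):
        # low gamma (~47 Hz) is the wake-marking rhythm inside the state-map
        # ratio denominators; high gamma (82 Hz) carries the theta coupling
        return {
            "pfc": [Oscillator(delta_center, delta_bw, delta_amp),
                    Oscillator(47.0, 12.0, low_gamma),
                    Oscillator(82.0, 30.0, pfc_gamma)],
            "hpc": [Oscillator(delta_center, delta_bw, delta_amp),
                    Oscillator(47.0, 12.0, low_gamma),
                    Oscillator(82.0, 30.0, hpc_gamma)],
        }

    common = dict(exponent={"pfc": exp_pfc, "hpc": exp_hpc},
                  offset={"pfc": 0.0, "hpc": 0.0})
    return {
        "ACT": StateParams(
            label="ACT", **common,
            theta_amp={"hpc": act_theta_hpc, "pfc": 0.8},
            oscillators=oscs(0.6, 0.5, 0.4, 0.15),
            theta_coherence=0.42 if els else 0.45,
            coupling_r=0.1 if els else 0.5,
            emg_var=4.0, dwell_s=150.0),
        "QWK": StateParams(
            label="QWK", **common,
            theta_amp={"hpc": 0.3, "pfc": 0.22},
            oscillators=oscs(0.45, 0.3, 0.3, 0.3),
            theta_coherence=0.30 if els else 0.05,
            coupling_r=0.1 if els else 0.4,
            emg_var=1.5, dwell_s=60.0),
        "NREM": StateParams(
            label="NREM", **common,
            theta_amp={"hpc": 0.3, "pfc": 0.2},
            oscillators=oscs(0.25, 0.25, 0.25, 1.5, delta_center=2.5,
                             delta_bw=2.0),
            theta_coherence=0.2, coupling_r=0.3,
            emg_var=0.3, dwell_s=200.0),
        "REM": StateParams(
            label="REM", **common,
            theta_amp={"hpc": 1.5, "pfc": 1.1},
            oscillators=oscs(0.12, 0.4, 0.35, 0.1),
            theta_coherence=0.45 if els else 0.60,
            coupling_r=0.3 if els else 0.5,
            emg_var=0.1, dwell_s=75.0),
    }


def ctrl_spec(fs: float = 500.0, duration_s: float = 1800.0,
              seed: int = 0) -> CohortSpec:
    """Control-group preset."""
    return CohortSpec(group="CTRL", states=_base_states("CTRL"),
                      transition=_default_transition(),
                      swd=SWDSpec(subject_prob=0.0),
                      fs=fs, duration_s=duration_s, seed=seed)


def els_spec(fs: float = 500.0, duration_s: float = 1800.0,
             seed: int = 0) -> CohortSpec:
    """Early-life-seizure preset: effect *directions* of the modeled group.

    Higher ACT HPC theta, lower REM coherence, flatter PFC spectrum, weaker
    theta-gamma coupling, REM-like ACT blocks, and SWDs expressed by ~44.5 %
    of subjects (mainly during NREM).
    """
    return CohortSpec(
        group="ELS", states=_base_states("ELS"),
        transition=_default_transition(),
        swd=SWDSpec(subject_prob=0.445,
                    rate_per_min={"NREM": 0.5, "QWK": 0.1, "ACT": 0.05},
                    duration_mean_s=6.614, duration_sd_s=0.283),
        fs=fs, duration_s=duration_s, seed=seed,
        act_rem_blend_prob=0.4, act_rem_blend_weight=1.0,
    )


def _jitter_spec(spec: CohortSpec, rng) -> CohortSpec:
    """Per-subject biological variability around the preset."""
    states = {}
    for label, p in spec.states.items():
        states[label] = replace(
            p,
            theta_amp={r: a * rng.lognormal(0, 0.08)
                       for r, a in p.theta_amp.items()},
            exponent={r: max(0.1, e + rng.normal(0, 0.05))
                      for r, e in p.exponent.items()},
            theta_coherence=float(np.clip(
                p.theta_coherence + rng.normal(0, 0.03), 0.02, 0.9)),
            coupling_r=float(np.clip(
                p.coupling_r + rng.normal(0, 0.05), 0.0, 0.95)),
            emg_var=p.emg_var * rng.lognormal(0, 0.1),
        )
    out = copy.copy(spec)
    out.states = states
    return out


def make_subject(spec: CohortSpec, subject: str, seed: int,
                 jitter: bool = True) -> tuple[Recording, GroundTruth]:
    """Generate one subject: jittered params, states, signal, SWDs."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(4) % (2 ** 31)
    sub_spec = _jitter_spec(spec, np.random.default_rng(int(seeds[0]))) \
        if jitter else spec
    states = sample_state_sequence(sub_spec, int(seeds[1]),
                                   require_all_states=True)
    rec, truth = synthesize_recording(sub_spec, states, int(seeds[2]))
    rec.subject = subject
    swd_rng = np.random.default_rng(int(seeds[3]))
    if sub_spec.swd.subject_prob > 0 and swd_rng.random() < sub_spec.swd.subject_prob:
        rec, truth = inject_swd(rec, truth, sub_spec, int(seeds[3]) + 1)
    truth.planted["spec"] = sub_spec
    return rec, truth


def make_cohort(n_ctrl: int, n_els: int, overrides: dict | None = None,
                seed: int = 0, fs: float = 500.0,
                duration_s: float = 1800.0) -> list[tuple[Recording, GroundTruth]]:
    """Generate a CTRL + ELS cohort with deterministic per-subject seeds."""
    overrides = overrides or {}
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_ctrl + n_els) % (2 ** 31)
    cohort = []
    for i in range(n_ctrl):
        spec = ctrl_spec(fs=fs, duration_s=duration_s)
        for k, v in overrides.get("CTRL", {}).items():
            setattr(spec, k, v)
        cohort.append(make_subject(spec, f"ctrl{i + 1:02d}", int(child[i])))
    for j in range(n_els):
        spec = els_spec(fs=fs, duration_s=duration_s)
        for k, v in overrides.get("ELS", {}).items():
            setattr(spec, k, v)
        cohort.append(make_subject(spec, f"els{j + 1:02d}",
                                   int(child[n_ctrl + j])))
    return cohort
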