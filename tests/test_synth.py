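"""Generator contracts: Markov architecture, planted-parameter recovery,
SWD injection, determinism."""

import numpy as np
import pytest

from lfpstates import spectral, synth
from lfpstates.specparam import parametrize_spectrum


def _const_spec(duration_s=600.0):
    return synth.ctrl_spec(duration_s=duration_s)


class TestStateSequence:
    def test_absorbing_state_stays_constant(self):
        spec = _const_spec()
        spec.transition = np.eye(4)
        seq = synth.sample_state_sequence(spec, seed=0)
        # the chain starts from the stationary draw and never leaves it
        assert len(set(seq)) == 1

    def test_occupancy_matches_stationary_vector(self):
        spec = _const_spec(duration_s=5e5)  # 1e5 epochs
        seq = synth.sample_state_sequence(spec, seed=1)
        pi = synth.stationary_distribution(spec.transition)
        for k, state in enumerate(synth.STATES):
            assert abs(np.mean(seq == state) - pi[k]) < 0.02

    def test_dwell_times_geometric_mean(self):
        spec = _const_spec(duration_s=3e5)
        seq = synth.sample_state_sequence(spec, seed=2)
        runs = {s: [] for s in synth.STATES}
        start = 0
        for i in range(1, len(seq) + 1):
            if i == len(seq) or seq[i] != seq[start]:
                runs[str(seq[start])].append(i - start)
                start = i
        for k, state in enumerate(synth.STATES):
            expected = 1.0 / (1.0 - spec.transition[k, k])
            assert np.mean(runs[state]) == pytest.approx(expected, rel=0.15)

    def test_deterministic_for_fixed_seed(self):
        spec = _const_spec()
        a = synth.sample_state_sequence(spec, seed=3)
        b = synth.sample_state_sequence(spec, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_non_stochastic_matrix_names_row(self):
        bad = _const_spec().transition.copy()
        bad[2, 2] += 0.1
        with pytest.raises(ValueError, match="row 2"):
            synth.validate_transition(bad)


class TestSynthesizeRecording:
    def test_bitwise_deterministic(self):
        spec = _const_spec(300)
        states = synth.sample_state_sequence(spec, 4)
        r1, _ = synth.synthesize_recording(spec, states, 5)
        r2, _ = synth.synthesize_recording(spec, states, 5)
        np.testing.assert_array_equal(r1.pfc, r2.pfc)
        np.testing.assert_array_equal(r1.emg, r2.emg)

    def test_zero_oscillators_recovers_pure_exponent(self):
        from dataclasses import replace
        spec = _const_spec(600)
        p0 = replace(spec.states["ACT"], theta_amp={"hpc": 0.0, "pfc": 0.0},
                     oscillators={"pfc": [], "hpc": []}, theta_coherence=0.0,
                     coupling_r=0.0)
        spec.states["ACT"] = p0
        states = np.array(["ACT"] * 120)
        rec, truth = synth.synthesize_recording(spec, states, 6)
        x = rec.pfc.reshape(-1, int(3 * rec.fs))
        est = spectral.welch_psd(x, rec.fs)
        fit = parametrize_spectrum(est.freqs, est.values.mean(axis=0))
        assert len(fit.peaks) == 0
        assert fit.exponent == pytest.approx(p0.exponent["pfc"], abs=0.15)

    def test_planted_rem_coherence_recovered(self, plain_ctrl_recording):
        spec, rec, truth = plain_ctrl_recording
        fs = rec.fs
        spe = int(5 * fs)
        idx = np.flatnonzero(truth.states_5s == "REM")
        h = np.stack([rec.hpc[i * spe:i * spe + int(3 * fs)] for i in idx])
        p = np.stack([rec.pfc[i * spe:i * spe + int(3 * fs)] for i in idx])
        coh = spectral.msc_coherence(h, p, fs)
        band = spectral.band_mean(
            spectral.SpectralEstimate(coh.freqs, coh.values.mean(axis=0)),
            "theta")
        assert band == pytest.approx(spec.states["REM"].theta_coherence,
                                     abs=0.1)

    def test_planted_lag_recovered(self, plain_ctrl_recording):
        spec, rec, truth = plain_ctrl_recording
        fs = rec.fs
        spe = int(5 * fs)
        idx = np.flatnonzero(truth.states_5s == "ACT")
        h = np.stack([rec.hpc[i * spe:i * spe + int(3 * fs)] for i in idx])
        p = np.stack([rec.pfc[i * spe:i * spe + int(3 * fs)] for i in idx])
        cg = spectral.cross_correlation(h, p, fs)
        lag, _ = spectral.peak_in_window(cg, -200.0, 200.0)
        assert lag == pytest.approx(-spec.states["ACT"].lag_ms, abs=10.0)

    def test_lag_exceeding_epoch_rejected(self):
        spec = _const_spec(300)
        with pytest.raises(ValueError):
            spec.states["ACT"].lag_ms = 6000.0
            synth.synthesize_recording(spec, np.array(["ACT"] * 60), 0)

    def test_within_state_stationarity(self):
        """PSD of same-state epochs: halves of the recording agree < 10 %."""
        spec = _const_spec(1200)
        states = np.array(["NREM"] * 240)
        rec, _ = synth.synthesize_recording(spec, states, 9)
        x = rec.hpc.reshape(-1, int(3 * rec.fs))
        est = spectral.welch_psd(x, rec.fs)
        half = len(x) // 2
        p1 = est.values[:half].mean(axis=0)
        p2 = est.values[half:].mean(axis=0)
        rel_l2 = np.linalg.norm(p1 - p2) / np.linalg.norm(p1)
        assert rel_l2 < 0.10


class TestInjectSWD:
    def test_zero_rate_leaves_recording_unchanged(self):
        spec = _const_spec(300)
        states = synth.sample_state_sequence(spec, 10)
        rec, truth = synth.synthesize_recording(spec, states, 11)
        rec2, truth2 = synth.inject_swd(rec, truth, spec, 12)
        np.testing.assert_array_equal(rec.pfc, rec2.pfc)
        assert truth2.swd_intervals == []

    def test_duration_distribution_monte_carlo(self):
        spec = synth.els_spec(duration_s=3600)
        spec.swd.rate_per_min = {"NREM": 2.0}
        spec.swd.duration_sd_s = 0.5
        durations = []
        seed = 0
        while len(durations) < 50:
            states = np.array(["NREM"] * 720)
            rec, truth = synth.synthesize_recording(
                synth.ctrl_spec(duration_s=3600), states, seed)
            _, t2 = synth.inject_swd(rec, truth, spec, seed + 1)
            durations += [e - s for s, e in t2.swd_intervals]
            seed += 2
        assert np.mean(durations[:50]) == pytest.approx(6.614, abs=0.3)

    def test_nrem_only_rates_respect_state(self):
        spec = synth.els_spec(duration_s=1800)
        spec.swd.rate_per_min = {"NREM": 1.0}
        states = synth.sample_state_sequence(spec, 13,
                                             require_all_states=True)
        rec, truth = synth.synthesize_recording(
            synth.ctrl_spec(duration_s=1800), states, 14)
        _, t2 = synth.inject_swd(rec, truth, spec, 15)
        assert len(t2.swd_intervals) > 0
        for s, e in t2.swd_intervals:
            ep_states = truth.states_5s[int(s // 5): int(np.ceil(e / 5))]
            assert set(ep_states) == {"NREM"}
            assert 0 <= s and e <= rec.duration


class TestMakeCohort:
    def test_empty_cohort(self):
        assert synth.make_cohort(0, 0, seed=0) == []

    def test_rerun_is_byte_identical(self):
        c1 = synth.make_cohort(1, 1, seed=5, duration_s=600)
        c2 = synth.make_cohort(1, 1, seed=5, duration_s=600)
        for (r1, t1), (r2, t2) in zip(c1, c2):
            np.testing.assert_array_equal(r1.pfc, r2.pfc)
            np.testing.assert_array_equal(t1.states_5s, t2.states_5s)
            assert t1.swd_intervals == t2.swd_intervals

    def test_subjects_have_all_states(self):
        for rec, truth in synth.make_cohort(2, 2, seed=6, duration_s=900):
            assert set(np.unique(truth.states_5s)) == set(synth.STATES)
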