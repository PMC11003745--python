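"""State-map construction, IS flagging, GMM validation, REM-ACT distance."""

import numpy as np
import pytest

from lfpstates.spectral import SpectralEstimate
from lfpstates.statemap import (StateMap, build_state_map, flag_intermediate,
                                hann_smooth, rem_act_distance,
                                spectral_ratios, trajectory_speed,
                                validate_clusters)


def _flat_psd(n_epochs=5):
    f = np.arange(0.5, 100.01, 0.5)
    return SpectralEstimate(freqs=f, values=np.ones((n_epochs, f.size)))


class TestSpectralRatios:
    def test_concentrated_power_gives_unit_ratio(self):
        f = np.arange(0.5, 100.01, 0.5)
        v = np.zeros((1, f.size))
        v[0, (f >= 4.5) & (f <= 9.0)] = 1.0
        r1, r2 = spectral_ratios(SpectralEstimate(f, v))
        assert r1[0] == pytest.approx(1.0)

    def test_flat_psd_bin_count_arithmetic(self):
        f = np.arange(0.5, 100.01, 0.5)
        r1, r2 = spectral_ratios(_flat_psd())
        n_num = np.sum((f >= 4.5) & (f <= 9.0))
        n_den = np.sum((f >= 4.5) & (f <= 50.0))
        assert np.allclose(r1, n_num / n_den)
        assert r1[0] == pytest.approx(0.0989, abs=0.02)

    def test_band_membership_of_tones(self):
        f = np.arange(0.5, 100.01, 0.5)
        # 30 Hz: inside both denominators, outside both numerators
        v = np.zeros((1, f.size))
        v[0, np.argmin(np.abs(f - 30.0))] = 1.0
        r1, r2 = spectral_ratios(SpectralEstimate(f, v))
        assert r1[0] == pytest.approx(0.0)
        assert r2[0] == pytest.approx(0.0)
        # 10 Hz: inside the ratio-2 numerator, outside the ratio-1 numerator
        v = np.zeros((1, f.size))
        v[0, np.argmin(np.abs(f - 10.0))] = 1.0
        r1, r2 = spectral_ratios(SpectralEstimate(f, v))
        assert r1[0] == pytest.approx(0.0)
        assert r2[0] == pytest.approx(1.0)

    def test_grid_coverage_required(self):
        f = np.arange(5.0, 40.0, 0.5)
        with pytest.raises(ValueError):
            spectral_ratios(SpectralEstimate(f, np.ones((1, f.size))))


class TestBuildStateMap:
    def test_identical_regions_give_common_series(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        m = build_state_map((x, y), (x, y))
        # rank-1 case: coordinate 1 proportional to the (smoothed) series
        sm = hann_smooth(x - x.mean())
        corr = np.corrcoef(m.coords[:, 0], sm)[0, 1]
        assert corr > 0.999

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance|constant"):
            build_state_map((np.ones(50), np.ones(50)),
                            (np.ones(50), np.ones(50)))

    def test_first_pc_matches_covariance_eigvector_oracle(self, rng):
        shared = rng.standard_normal(400)
        a = shared + 0.3 * rng.standard_normal(400)
        b = -shared + 0.3 * rng.standard_normal(400)  # anti-correlated regions
        from lfpstates.statemap import _first_pc_score
        score = _first_pc_score(a, b, standardize=True)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        C = np.cov(np.stack([za, zb]))
        w, v = np.linalg.eigh(C)
        lead = v[:, np.argmax(w)]
        oracle = np.stack([za, zb]).T @ lead
        r = abs(np.corrcoef(score, oracle)[0, 1])
        assert r > 0.999
        # variance explained matches the leading eigenvalue share
        assert np.var(score) / (np.var(za) + np.var(zb)) == pytest.approx(
            w.max() / w.sum(), rel=1e-6)

    def test_smoothing_preserves_constants_and_reduces_variance(self, rng):
        const = np.full(64, 3.14)
        np.testing.assert_allclose(hann_smooth(const), const, rtol=1e-12)
        x = rng.standard_normal(256)
        assert hann_smooth(x).var() <= x.var()

    def test_sign_convention_positive_with_hpc(self, rng):
        x = rng.standard_normal(100)
        y = 0.5 * x + 0.1 * rng.standard_normal(100)
        m = build_state_map((x, y), (x, y))
        assert np.corrcoef(m.coords[:, 0], x)[0, 1] > 0


class TestTrajectorySpeed:
    def test_constant_trajectory_no_is(self):
        m = StateMap(coords=np.ones((30, 2)))
        m.speeds = trajectory_speed(m)
        assert np.isnan(m.speeds[0])
        assert np.all(m.speeds[1:] == 0)
        assert not flag_intermediate(m).any()

    def test_step_of_point_two_flagged(self):
        coords = np.zeros((10, 2))
        coords[5:, 0] = 0.2
        m = StateMap(coords=coords)
        m.speeds = trajectory_speed(m)
        flags = flag_intermediate(m)
        assert flags[5]
        assert flags.sum() == 1

    def test_speeds_match_bruteforce_distances(self, rng):
        coords = rng.standard_normal((40, 2))
        m = StateMap(coords=coords)
        speeds = trajectory_speed(m)
        for i in range(1, 40):
            d = np.sqrt(((coords[i] - coords[i - 1]) ** 2).sum())
            assert speeds[i] == pytest.approx(d, rel=1e-12)

    def test_translation_invariance(self, rng):
        coords = rng.standard_normal((40, 2))
        s1 = trajectory_speed(StateMap(coords=coords))
        s2 = trajectory_speed(StateMap(coords=coords + 7.7))
        np.testing.assert_allclose(s1[1:], s2[1:], rtol=1e-9)


class TestValidateClusters:
    def test_separated_clouds_recovered(self, rng):
        centers = {"ACT": (0, 0), "NREM": (6, 0), "REM": (0, 6)}
        pts, labels = [], []
        for state, c in centers.items():
            pts.append(rng.normal(c, 0.4, size=(80, 2)))
            labels += [state] * 80
        m = StateMap(coords=np.vstack(pts))
        m.speeds = trajectory_speed(m)
        m.is_flags = flag_intermediate(m)
        val = validate_clusters(m, np.array(labels), seed=0)
        assert val.purity >= 0.9
        assert val.p_value < 1e-10
        assert not val.low_correspondence

    def test_single_cloud_flags_low_correspondence(self, rng):
        m = StateMap(coords=rng.normal(0, 1, size=(240, 2)))
        m.speeds = trajectory_speed(m)
        m.is_flags = flag_intermediate(m)
        labels = rng.choice(["ACT", "NREM", "REM"], size=240)
        val = validate_clusters(m, labels, seed=0)
        assert val.low_correspondence

    def test_posterior_threshold_excludes_boundary(self, rng):
        """Points midway between two overlapping components stay unassigned."""
        a = np.column_stack([rng.normal(-1.5, 1, 200), rng.normal(0, 1, 200)])
        b = np.column_stack([rng.normal(+1.5, 1, 200), rng.normal(0, 1, 200)])
        c = rng.normal((0, 8), 0.3, size=(100, 2))
        m = StateMap(coords=np.vstack([a, b, c]))
        m.speeds = trajectory_speed(m)
        m.is_flags = flag_intermediate(m)
        labels = np.array(["ACT"] * 200 + ["NREM"] * 200 + ["REM"] * 100)
        val = validate_clusters(m, labels, seed=0)
        boundary = (np.abs(m.coords[:, 0]) < 0.3) & (np.abs(m.coords[:, 1]) < 1)
        assert boundary.sum() > 10
        assert (val.cluster[boundary] == -1).mean() > 0.5
        # far-cluster points are confidently assigned
        assert (val.cluster[-100:] >= 0).mean() > 0.95


class TestRemActDistance:
    def test_pythagorean_case(self):
        coords = np.vstack([np.zeros((5, 2)), np.tile([3.0, 4.0], (5, 1))])
        labels = np.array(["REM"] * 5 + ["ACT"] * 5)
        m = StateMap(coords=coords, is_flags=np.zeros(10, dtype=bool))
        d = rem_act_distance(m, labels)
        assert d["mean_distance"] == pytest.approx(5.0)

    def test_identical_clouds_equal_intra_distance(self, rng):
        pts = rng.standard_normal((40, 2))
        coords = np.vstack([pts, pts])
        labels = np.array(["REM"] * 40 + ["ACT"] * 40)
        m = StateMap(coords=coords, is_flags=np.zeros(80, dtype=bool))
        d = rem_act_distance(m, labels)
        brute = np.mean([np.linalg.norm(p - q) for p in pts for q in pts])
        assert d["mean_distance"] == pytest.approx(brute, rel=1e-9)

    def test_absent_state_named(self):
        m = StateMap(coords=np.zeros((5, 2)), is_flags=np.zeros(5, dtype=bool))
        with pytest.raises(ValueError, match="REM"):
            rem_act_distance(m, np.array(["ACT"] * 5))

    def test_translation_invariance(self, rng):
        coords = rng.standard_normal((60, 2))
        labels = np.array(["REM"] * 30 + ["ACT"] * 30)
        m1 = StateMap(coords=coords, is_flags=np.zeros(60, dtype=bool))
        m2 = StateMap(coords=coords + 5.0, is_flags=np.zeros(60, dtype=bool))
        assert rem_act_distance(m1, labels)["mean_distance"] == pytest.approx(
            rem_act_distance(m2, labels)["mean_distance"], rel=1e-9)
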