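"""Cleaning, dispersion-based fixation detection, saccades and kinematics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from gazefatigue.events import (
    EventConfig,
    clean_recording,
    compute_kinematics,
    derive_saccades,
    detect_fixations,
)
from gazefatigue.recording import GazeRecording

from conftest import make_recording, piecewise_fixations


def brute_force_fixations(rec, cfg):
    """Independent I-DT oracle: same greedy policy, but dispersion fully
    recomputed with scipy's pairwise distances at every candidate window."""
    out = []
    for lo, hi in rec.valid_segments():
        i = lo
        while i < hi:
            b = i
            for j in range(i + 1, hi):
                pts = np.column_stack([rec.x[i : j + 1], rec.y[i : j + 1]])
                if pdist(pts).max() > cfg.area_diameter:
                    break
                b = j
            if b > i and rec.t[b] - rec.t[i] >= cfg.min_fixation_duration:
                out.append((i, b))
                i = b + 1
            else:
                i += 1
    return out


class TestCleanRecording:
    def test_clean_recording_identity_without_invalid(self, stationary_1s):
        cfg = EventConfig()
        out = clean_recording(stationary_1s, cfg)
        np.testing.assert_array_equal(out.x, stationary_1s.x)
        assert out.valid.all()

    def test_single_invalid_sample_linearly_interpolated(self):
        rec = make_recording([0.0, 0.01, 0.02], [0.0, np.nan, 1.0], [0.0, np.nan, 0.0])
        out = clean_recording(rec, EventConfig())
        assert out.valid.all()
        assert out.x[1] == pytest.approx(0.5)
        assert out.y[1] == pytest.approx(0.0)

    def test_long_gap_splits_into_segments(self):
        rate = 100.0
        t = np.arange(500) / rate
        x = np.zeros(500)
        valid = np.ones(500, bool)
        valid[150:350] = False  # 2 s gap >> 0.075 s
        x[~valid] = np.nan
        rec = make_recording(t, x, np.zeros(500), valid=valid)
        out = clean_recording(rec, EventConfig(max_gap_interpolation=0.075))
        segs = list(out.valid_segments())
        assert len(segs) == 2
        assert sum(hi - lo for lo, hi in segs) == 300  # no samples fabricated
        assert len(out) == 500


class TestDetectFixations:
    def test_stationary_second_is_one_fixation(self, stationary_1s):
        fx = detect_fixations(stationary_1s, EventConfig())
        assert len(fx) == 1
        f = fx[0]
        assert f.duration == pytest.approx(0.99, abs=1e-9)
        assert f.dispersion == 0.0

    def test_two_epochs_with_jump_give_two_fixations(self):
        rec = piecewise_fixations([0.5, 0.5], jump=20.0)
        fx = detect_fixations(rec, EventConfig())
        assert len(fx) == 2
        (c1x, _), (c2x, _) = fx[0].centroid, fx[1].centroid
        assert abs(c2x - c1x) == pytest.approx(20.0)

    def test_dispersion_never_exceeds_diameter(self, rng):
        cfg = EventConfig(area_diameter=0.8)
        for _ in range(10):
            n = rng.integers(50, 400)
            x = np.cumsum(rng.normal(0, 0.2, n))
            y = np.cumsum(rng.normal(0, 0.2, n))
            rec = make_recording(np.arange(n) / 100.0, x, y)
            for f in detect_fixations(rec, cfg):
                assert f.dispersion <= cfg.area_diameter + 1e-12

    @pytest.mark.parametrize("diameter", [0.3, 1.0])
    def test_matches_brute_force_oracle_on_fuzzed_recordings(self, rng, diameter):
        cfg = EventConfig(area_diameter=diameter)
        for _ in range(25):
            n = int(rng.integers(30, 300))
            # random walk with occasional jumps, plus dropout
            x = np.cumsum(rng.normal(0, 0.15, n))
            y = np.cumsum(rng.normal(0, 0.15, n))
            jumps = rng.integers(0, n, size=3)
            x[jumps.min():] += 5.0
            valid = rng.uniform(size=n) > 0.05
            x = np.where(valid, x, np.nan)
            rec = make_recording(np.arange(n) / 100.0, x, y, valid=valid)
            got = [(f.start_idx, f.end_idx) for f in detect_fixations(rec, cfg)]
            assert got == brute_force_fixations(rec, cfg)

    def test_time_conservation_within_segment(self, rng):
        n = 600
        x = np.cumsum(rng.normal(0, 0.3, n))
        rec = make_recording(np.arange(n) / 100.0, x, np.zeros(n))
        cfg = EventConfig()
        fx = detect_fixations(rec, cfg)
        sc = derive_saccades(rec, fx)
        covered = sum(f.duration for f in fx) + sum(s.duration for s in sc)
        unclassified = rec.duration - covered
        # events tile the recording up to scan leftovers at segment edges
        assert -1e-9 <= unclassified <= rec.duration


class TestDeriveSaccades:
    def test_three_four_five_amplitude(self):
        rec1 = piecewise_fixations([0.5], jump=0.0)
        # two fixations at (0,0) and (3,4)
        n = 50
        t = np.concatenate([np.arange(n) / 100.0, 0.5 + np.arange(n) / 100.0])
        x = np.concatenate([np.zeros(n), np.full(n, 3.0)])
        y = np.concatenate([np.zeros(n), np.full(n, 4.0)])
        rec = make_recording(t, x, y)
        fx = detect_fixations(rec, EventConfig())
        sc = derive_saccades(rec, fx)
        assert len(sc) == 1
        assert sc[0].length == pytest.approx(5.0)

    def test_single_fixation_yields_no_saccade(self, stationary_1s):
        fx = detect_fixations(stationary_1s, EventConfig())
        assert derive_saccades(stationary_1s, fx) == []

    def test_no_saccade_across_segment_boundary(self):
        rate = 100.0
        n = 100
        t = np.arange(2 * n + 50) / rate
        x = np.concatenate([np.zeros(n), np.full(50, np.nan), np.full(n, 20.0)])
        valid = np.isfinite(x)
        rec = make_recording(t, x, np.zeros_like(x), valid=valid)
        rec = clean_recording(rec, EventConfig())
        fx = detect_fixations(rec, EventConfig())
        assert len(fx) == 2
        assert derive_saccades(rec, fx) == []


class TestKinematics:
    def test_straight_uniform_motion_has_zero_curvature(self):
        t = np.arange(200) / 100.0
        rec = make_recording(t, 10.0 * t, 5.0 * t)
        kin = compute_kinematics(rec)
        np.testing.assert_allclose(kin.curvature, 0.0, atol=1e-9)

    @pytest.mark.parametrize("radius", [2.0, 5.0, 10.0])
    def test_circle_gives_curvature_one_over_radius(self, radius):
        theta = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        rec = make_recording(
            np.arange(theta.size) / 100.0,
            radius * np.cos(theta),
            radius * np.sin(theta),
        )
        kin = compute_kinematics(rec)
        np.testing.assert_allclose(kin.curvature, 1.0 / radius, rtol=1e-6)

    def test_constant_speed_drift(self):
        t = np.arange(300) / 100.0
        rec = make_recording(t, 10.0 * t, np.zeros_like(t))
        kin = compute_kinematics(rec)
        np.testing.assert_allclose(kin.velocity, 10.0, rtol=1e-9)
        np.testing.assert_allclose(kin.accel_mag, 0.0, atol=1e-7)
        np.testing.assert_allclose(kin.second_v_min, 10.0, rtol=1e-9)

    def test_invariant_under_rotation_and_translation(self, rng):
        n = 400
        t = np.arange(n) / 100.0
        x = np.cumsum(rng.normal(0, 0.1, n))
        y = np.cumsum(rng.normal(0, 0.1, n))
        kin1 = compute_kinematics(make_recording(t, x, y))
        ang = 0.7
        xr = 3.0 + x * np.cos(ang) - y * np.sin(ang)
        yr = -2.0 + x * np.sin(ang) + y * np.cos(ang)
        kin2 = compute_kinematics(make_recording(t, xr, yr))
        np.testing.assert_allclose(kin2.velocity, kin1.velocity, rtol=1e-9)
        np.testing.assert_allclose(kin2.curvature, kin1.curvature, rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(kin2.accel_mag, kin1.accel_mag, rtol=1e-7, atol=1e-9)
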