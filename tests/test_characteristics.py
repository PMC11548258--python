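"""The characteristic catalogue, summary statistics and feature matrices."""

import numpy as np
import pandas as pd
import pytest

from gazefatigue.characteristics import (
    CATALOGUE,
    CATALOGUE_KEYS,
    SELECTED_CHARACTERISTICS,
    build_feature_matrix,
    feature_columns,
    recording_characteristics,
    summarize_series,
    windowed_characteristics,
)
from gazefatigue.events import EventConfig
from gazefatigue.recording import GazeDataError, InvalidParameterError
from gazefatigue.simulate import (
    FatigueEffectConfig,
    SimParams,
    StudyDesign,
    simulate_recording,
    simulate_study,
)

from conftest import make_recording, piecewise_fixations


class TestCatalogue:
    def test_has_27_entries_and_7_selected(self):
        assert len(CATALOGUE) == 27
        assert len(SELECTED_CHARACTERISTICS) == 7
        assert set(SELECTED_CHARACTERISTICS) <= set(CATALOGUE_KEYS)

    def test_duration_bin_counting(self):
        # detected durations: (n-1)/rate -> 0.09, 0.19, 0.99 s
        rec = piecewise_fixations([0.1, 0.2, 1.0])
        vec = recording_characteristics(rec, EventConfig())
        assert vec["pct_fixations_lt_150"] == pytest.approx(100.0 / 3.0)
        assert vec["pct_fixations_ge_150"] == pytest.approx(200.0 / 3.0)
        minutes = rec.duration / 60.0
        assert vec["fixations_ge_900_per_minute"] == pytest.approx(1.0 / minutes)

    def test_velocity_vs_speed_in_fixation(self):
        # straight drift at 2 deg/s inside one fixation
        t = np.arange(100) / 100.0
        rec = make_recording(t, 2.0 * t, np.zeros_like(t))
        vec = recording_characteristics(rec, EventConfig(area_diameter=3.0))
        assert vec["fixation_velocity_mean"] == pytest.approx(2.0, rel=1e-6)
        assert vec["fixation_speed_mean"] == pytest.approx(2.0, rel=1e-6)
        # zig-zag with the same net displacement doubles the path, so the
        # speed doubles while the velocity stays put
        y = np.where(np.arange(100) % 2 == 0, 0.0, 2.0 / 100.0 * np.sqrt(3.0))
        zig = make_recording(t, 2.0 * t, y)
        vz = recording_characteristics(zig, EventConfig(area_diameter=3.0))
        assert vz["fixation_velocity_mean"] == pytest.approx(
            vec["fixation_velocity_mean"], rel=1e-2
        )
        assert vz["fixation_speed_mean"] > 1.8 * vec["fixation_speed_mean"]

    def test_complement_and_partition_identities(self):
        rec = simulate_recording(SimParams(), 30.0, seed=42)
        vec = recording_characteristics(rec, EventConfig())
        assert vec["pct_fixations_lt_150"] + vec["pct_fixations_ge_150"] == 100.0
        assert vec["pct_fixations_lt_180"] + vec["pct_fixations_ge_180"] == 100.0
        assert (
            vec["time_share_fixations_lt_150"] + vec["time_share_fixations_ge_150"]
        ) == pytest.approx(100.0, abs=1e-9)
        # the three duration bins partition total fixation time
        ge900_share = (
            vec["time_share_fixations_ge_150"] - vec["time_share_fixations_150_900"]
        )
        total = (
            vec["time_share_fixations_lt_150"]
            + vec["time_share_fixations_150_900"]
            + ge900_share
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_min_le_mean_le_max_triples(self):
        rec = simulate_recording(SimParams(), 30.0, seed=7)
        vec = recording_characteristics(rec, EventConfig())
        for lo, mid, hi in [
            ("curvature_min", "curvature_mean", "curvature_max"),
            ("saccade_length_min", "saccade_length_mean", "saccade_length_max"),
        ]:
            assert vec[lo] <= vec[mid] <= vec[hi]
        assert vec["fixation_velocity_min"] <= vec["fixation_velocity_mean"]
        assert vec["saccade_duration_mean"] <= vec["saccade_duration_max"]

    def test_time_dilation_scales_rates_not_percentages(self):
        # same events on a 2x slower clock: percentages unchanged, per-minute
        # counts halved (durations chosen away from the bin boundaries)
        rec = piecewise_fixations([0.4, 0.4, 0.4])
        slow = make_recording(rec.t * 2.0, rec.x, rec.y)
        v1 = recording_characteristics(rec, EventConfig())
        v2 = recording_characteristics(slow, EventConfig())
        assert v2["pct_fixations_150_900"] == v1["pct_fixations_150_900"] == 100.0
        assert v2["fixations_lt_180_per_minute"] == pytest.approx(
            v1["fixations_lt_180_per_minute"] / 2.0
        )

    def test_mismatched_events_rejected(self):
        from gazefatigue.events import clean_recording, compute_kinematics, \
            derive_saccades, detect_fixations
        from gazefatigue.characteristics import compute_characteristics

        cfg = EventConfig()
        rec = clean_recording(simulate_recording(SimParams(), 10.0, seed=1), cfg)
        fx = detect_fixations(rec, cfg)
        kin = compute_kinematics(rec)
        with pytest.raises(GazeDataError):
            compute_characteristics(rec, fx, [], kin, cfg.with_diameter(2.0))


class TestSummarizeSeries:
    def test_constant_series(self):
        s = summarize_series([3.5] * 10)
        assert s.mean == s.minimum == s.maximum == s.p25 == s.p50 == s.p75 == 3.5
        assert s.sd == 0.0

    def test_one_to_hundred(self):
        s = summarize_series(np.arange(1, 101, dtype=float))
        assert s.mean == pytest.approx(50.5)
        assert s.p50 == pytest.approx(50.5)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        vals = rng.normal(size=37)
        s = summarize_series(vals)
        srt = np.sort(vals)

        def pctl(q):  # independent linear-interpolation percentile
            pos = q / 100.0 * (len(srt) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(srt) - 1)
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        assert s.p25 == pytest.approx(pctl(25), abs=1e-12)
        assert s.p50 == pytest.approx(pctl(50), abs=1e-12)
        assert s.p75 == pytest.approx(pctl(75), abs=1e-12)
        assert s.sd == pytest.approx(np.std(vals, ddof=1), abs=1e-12)

    def test_empty_errors_but_all_nan_is_absent(self):
        with pytest.raises(GazeDataError):
            summarize_series([])
        assert summarize_series([np.nan, np.nan]) is None


class TestWindowedCharacteristics:
    def test_window_alignment(self):
        rec = simulate_recording(SimParams(), 60.0, seed=2)
        out = windowed_characteristics(rec, window_s=30.0, step_s=10.0)
        assert list(out.index) == pytest.approx([30.0, 40.0, 50.0, 60.0])

    def test_stationary_recording_gives_identical_windows(self):
        rec = piecewise_fixations([40.0])
        out = windowed_characteristics(rec, window_s=10.0, step_s=10.0)
        first = out.iloc[0]
        for _, row in out.iterrows():
            pd.testing.assert_series_equal(row, first, check_names=False)

    def test_window_longer_than_recording_is_empty(self):
        rec = piecewise_fixations([5.0])
        out = windowed_characteristics(rec, window_s=30.0, step_s=1.0)
        assert out.empty

    def test_rejects_tiny_window(self):
        rec = piecewise_fixations([10.0])
        with pytest.raises(InvalidParameterError):
            windowed_characteristics(rec, window_s=2.0, step_s=1.0)


@pytest.fixture(scope="module")
def study():
    design = StudyDesign(
        n_participants=2, n_days=1, sessions_per_day=2,
        session_duration=20.0, seed=9,
    )
    return simulate_study(design, FatigueEffectConfig())


class TestFeatureMatrix:
    def test_selected_set_has_seven_columns(self, study):
        m = build_feature_matrix(study, feature_sets="selected")
        assert len(feature_columns(m)) == 7

    def test_union_adds_disjoint_column_counts(self, study):
        m = build_feature_matrix(study, feature_sets="coordinates+selected")
        assert len(feature_columns(m)) == 21 + 7

    def test_unknown_token_rejected(self, study):
        with pytest.raises(InvalidParameterError):
            build_feature_matrix(study, feature_sets="everything")

    def test_rebuild_is_deterministic(self, study):
        m1 = build_feature_matrix(study, feature_sets="selected")
        m2 = build_feature_matrix(study, feature_sets="selected")
        pd.testing.assert_frame_equal(m1, m2)

    def test_windowing_multiplies_rows(self, study):
        m = build_feature_matrix(study, feature_sets="selected", samples_per_session=3)
        assert len(m) == 3 * len(study)
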