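"""Window segmentation and the 107-feature contract.

Golden values pin the statistic conventions; a brute-force oracle checks the
vectorized implementation; hypothesis covers the covariance properties.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import gaitmood as gm
from gaitmood.features import (
    STAT_NAMES,
    WindowSpec,
    angle_features,
    axis_stats,
    build_dataset,
    build_feature_vector,
    feature_names,
    magnitude_sd,
    segment_windows,
)
from gaitmood.preprocessing import FilterSpec
from gaitmood.sensor_io import HeartRateSeries, SensorRecording, WalkSegment

from _oracle import oracle_angles, oracle_axis_stats, oracle_magnitude_sd
from conftest import make_walk_segment as _segment_of_length


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "n,expected", [(24, 1), (48, 3), (23, 0), (0, 0), (36, 2), (35, 1)]
    )
    def test_default_window_counts(self, n, expected):
        assert len(segment_windows(n)) == expected

    def test_windows_are_half_open_and_regular(self):
        wins = segment_windows(60, WindowSpec(24, 12))
        assert wins == [(0, 24), (12, 36), (24, 48), (36, 60)]

    @given(st.integers(0, 5000), st.integers(2, 64), st.integers(1, 64))
    def test_count_matches_closed_form(self, n, length, step):
        step = min(step, length)
        wins = segment_windows(n, WindowSpec(length, step))
        expected = 0 if n < length else (n - length) // step + 1
        assert len(wins) == expected
        assert all(e - s == length for s, e in wins)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(1, 1)
        with pytest.raises(ValueError):
            WindowSpec(24, 25)


class TestAxisStats:
    def test_golden_values_1234(self):
        s = axis_stats([1, 2, 3, 4])
        assert s["mean"] == pytest.approx(2.5)
        assert s["sum"] == pytest.approx(10.0)
        assert s["min"] == 1.0 and s["max"] == 4.0
        assert s["range"] == pytest.approx(3.0)
        assert s["median"] == pytest.approx(2.5)
        assert s["rms"] == pytest.approx(np.sqrt(30 / 4))
        assert s["rss"] == pytest.approx(np.sqrt(30))

    def test_degenerate_constant_window(self):
        s = axis_stats([5, 5, 5, 5])
        assert s["sd"] == 0.0
        assert s["mad"] == 0.0
        assert s["skewness"] == 0.0
        assert s["kurtosis"] == 0.0
        assert s["energy"] == pytest.approx(25.0)

    def test_exactly_17_statistics(self, rng):
        s = axis_stats(rng.normal(size=24))
        assert len(s) == 17
        assert list(s) == STAT_NAMES

    def test_matches_bruteforce_oracle_on_random_windows(self, rng):
        """1000 random small windows: every statistic to 1e-9."""
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            w = rng.normal(scale=rng.uniform(0.1, 10), size=n)
            ours = axis_stats(w)
            ref = oracle_axis_stats(w)
            for name in STAT_NAMES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-9), name

    def test_window_shorter_than_two_rejected(self):
        with pytest.raises(ValueError):
            axis_stats([1.0])

    @given(
        hnp.arrays(np.int64, st.integers(4, 24), elements=st.integers(-100, 100)),
        st.integers(-40, 40),
    )
    def test_translation_covariance(self, w, c):
        # half-integer grids keep the arithmetic exact, so the algebraic
        # identity is testable without float-cancellation artefacts
        w, c = w / 2.0, c / 2.0
        base, shifted = axis_stats(w), axis_stats(w + c)
        for name in ("mean", "min", "max", "median", "q25", "q75"):
            assert shifted[name] == pytest.approx(base[name] + c, abs=1e-8)
        assert shifted["sum"] == pytest.approx(base["sum"] + c * len(w), abs=1e-7)
        for name in ("sd", "mad", "range", "skewness", "kurtosis"):
            assert shifted[name] == pytest.approx(base[name], abs=1e-6)

    @given(
        hnp.arrays(np.int64, st.integers(4, 24), elements=st.integers(-100, 100)),
        st.floats(0.01, 20),
    )
    def test_scale_covariance(self, w, s):
        w = w / 2.0
        base, scaled = axis_stats(w), axis_stats(s * w)
        for name in ("sd", "rms", "rss", "mad", "range"):
            assert scaled[name] == pytest.approx(s * base[name], rel=1e-8, abs=1e-8)
        for name in ("skewness", "kurtosis"):
            assert scaled[name] == pytest.approx(base[name], abs=1e-6)


class TestAngleAndMagnitude:
    def test_axis_aligned_mean_vector(self):
        w = np.tile([1.0, 0.0, 0.0], (4, 1))
        assert np.allclose(angle_features(w), [0.0, 90.0, 90.0])

    def test_diagonal_mean_vector(self):
        w = np.tile([1.0, 1.0, 1.0], (4, 1))
        assert np.allclose(angle_features(w), np.degrees(np.arccos(1 / np.sqrt(3))))

    def test_zero_mean_vector_convention(self):
        assert np.allclose(angle_features(np.zeros((4, 3))), 90.0)

    def test_constant_magnitude_rotation_has_zero_sd(self):
        w = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        assert magnitude_sd(w) == pytest.approx(0.0)

    def test_two_sample_magnitude_sd(self):
        w = np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 0.0]])
        assert magnitude_sd(w) == pytest.approx(np.std([5.0, 0.0], ddof=1))

    def test_matches_oracle_on_random_windows(self, rng):
        for _ in range(200):
            w = rng.normal(size=(int(rng.integers(2, 30)), 3))
            assert np.allclose(angle_features(w), oracle_angles(w), atol=1e-9)
            assert magnitude_sd(w) == pytest.approx(oracle_magnitude_sd(w), abs=1e-9)


class TestBuildFeatureVector:
    def test_exactly_107_values_and_102_motion_stats(self, rng):
        vec = build_feature_vector(
            rng.normal(size=(24, 3)), rng.normal(size=(24, 3)), 72.0
        )
        names = feature_names()
        assert vec.size == len(names) == 107
        motion = [n for n in names if n.startswith(("acc_", "gyro_"))]
        assert len(motion) == 102
        assert names[-1] == "heart_rate" and vec[-1] == 72.0

    def test_all_zero_windows(self):
        vec = build_feature_vector(np.zeros((24, 3)), np.zeros((24, 3)), 60.0)
        named = dict(zip(feature_names(), vec))
        assert named["heart_rate"] == 60.0
        assert named["angle_x"] == named["angle_y"] == named["angle_z"] == 90.0
        assert all(
            v == 0.0
            for k, v in named.items()
            if k not in ("heart_rate", "angle_x", "angle_y", "angle_z")
        )

    def test_mismatched_window_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="match"):
            build_feature_vector(
                rng.normal(size=(24, 3)), rng.normal(size=(12, 3)), 60.0
            )

    def test_vectorized_dataset_agrees_with_single_window_path(self, tiny_cohort):
        """The batched stats in build_dataset equal build_feature_vector."""
        from gaitmood.preprocessing import align_heart_rate, extract_walk, mean_filter

        seg = tiny_cohort[0]
        matrix = build_dataset([seg])
        rec = extract_walk(seg.recording, seg.start_s, seg.stop_s)
        accel = mean_filter(rec.accel, FilterSpec())
        s, e = segment_windows(len(rec))[5]
        hr = align_heart_rate(seg.heart_rate, rec.timestamps[s], rec.timestamps[e - 1])
        vec = build_feature_vector(accel[s:e], rec.gyro[s:e], hr)
        row = matrix.frame.iloc[5][matrix.feature_names].to_numpy(dtype=float)
        assert np.allclose(row, vec, atol=1e-10)




class TestBuildDataset:
    def test_one_48_sample_walk_gives_3_rows_same_label(self):
        matrix = build_dataset([_segment_of_length(48)])
        assert len(matrix) == 3
        assert set(matrix.y) == {"happy"}
        assert list(matrix.frame["window_index"]) == [0, 1, 2]

    def test_equal_duration_walks_have_equal_class_counts(self):
        segs = [
            _segment_of_length(480, "happy", seed=1),
            _segment_of_length(480, "sad", seed=2),
        ]
        counts = build_dataset(segs).class_counts
        assert counts["happy"] == counts["sad"]

    @pytest.mark.parametrize(
        "subset,n_cols", [("acc", 55), ("acc+hr", 56), ("acc+gyro+hr", 107)]
    )
    def test_sensor_subset_column_counts(self, subset, n_cols):
        matrix = build_dataset([_segment_of_length(48)], sensor_subset=subset)
        assert len(matrix.feature_names) == n_cols

    def test_too_short_walk_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="gaitmood.features"):
            matrix = build_dataset(
                [_segment_of_length(20, "sad"), _segment_of_length(48, "happy")]
            )
        assert "skipped" in caplog.text
        assert set(matrix.y) == {"happy"}

    @given(st.lists(st.integers(10, 400), min_size=1, max_size=6))
    def test_row_count_matches_window_bookkeeping(self, lengths):
        """Rows = sum over walks of floor((n-24)/12)+1 when n >= 24."""
        segs = [
            _segment_of_length(n, "happy" if i % 2 else "sad", f"p{i:02d}", seed=i)
            for i, n in enumerate(lengths)
        ]
        expected = sum((n - 24) // 12 + 1 for n in lengths if n >= 24)
        if expected == 0:
            with pytest.raises(ValueError):
                build_dataset(segs)
        else:
            assert len(build_dataset(segs)) == expected

    def test_all_values_finite(self, tiny_matrix):
        assert np.isfinite(tiny_matrix.X).all()
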