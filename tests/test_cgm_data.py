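"""CGM reading, cleaning, windowing, labeling, and splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyco.cgm_data import (BinaryLabel, GlucoseSeries, GlycemicLabel,
                            assign_labels, classify_bg, make_segments,
                            read_cgm_csv, read_ohio_xml, rescale,
                            segments_duration_hours, smooth,
                            split_target_patient, write_cgm_csv)


def series_from_values(values, patient="p1"):
    v = np.asarray(values, dtype=float)
    return GlucoseSeries(patient_id=patient, values=v, gap_mask=np.isnan(v))


def write_csv(tmp_path, rows, name="cgm.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["patient_id", "timestamp", "glucose_mgdl"]
                 ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

class TestReadCsv:
    def test_contiguous_samples_parse_without_gaps(self, tmp_path):
        path = write_csv(tmp_path, [("p1", 0, 100), ("p1", 5, 110), ("p1", 10, 120)])
        (series,) = read_cgm_csv(path)
        assert len(series) == 3
        assert not series.gap_mask.any()
        np.testing.assert_array_equal(series.values, [100, 110, 120])

    def test_skipped_grid_point_becomes_gap(self, tmp_path):
        path = write_csv(tmp_path, [("p1", 0, 100), ("p1", 5, 110), ("p1", 15, 120)])
        (series,) = read_cgm_csv(path)
        assert len(series) == 4
        np.testing.assert_array_equal(series.gap_mask, [False, False, True, False])

    def test_value_below_sensor_floor_rejected(self, tmp_path):
        path = write_csv(tmp_path, [("p1", 0, 30)])
        with pytest.raises(ValueError, match="sensor range"):
            read_cgm_csv(path)

    def test_value_outside_plausible_units_rejected(self, tmp_path):
        path = write_csv(tmp_path, [("p1", 0, 0.1)])
        with pytest.raises(ValueError, match="units"):
            read_cgm_csv(path)

    def test_non_monotone_timestamp_reports_row(self, tmp_path):
        path = write_csv(tmp_path, [("p1", 0, 100), ("p1", 10, 110), ("p1", 5, 105)])
        with pytest.raises(ValueError, match="row 2"):
            read_cgm_csv(path)

    def test_empty_file_rejected(self, tmp_path):
        path = write_csv(tmp_path, [])
        with pytest.raises(ValueError, match="empty"):
            read_cgm_csv(path)

    def test_iso_timestamps_and_multiple_patients(self, tmp_path):
        rows = [("a", "2024-01-01T00:00:00", 100), ("a", "2024-01-01T00:05:00", 105),
                ("b", "2024-01-02T08:00:00", 90), ("b", "2024-01-02T08:05:00", 95)]
        path = write_csv(tmp_path, rows)
        series = read_cgm_csv(path)
        assert [s.patient_id for s in series] == ["a", "b"]
        assert all(len(s) == 2 for s in series)

    def test_roundtrip_through_writer(self, tmp_path):
        original = series_from_values([100, np.nan, 120, 130])
        path = tmp_path / "out.csv"
        write_cgm_csv([original], path)
        (back,) = read_cgm_csv(path)
        np.testing.assert_array_equal(back.gap_mask, original.gap_mask)
        np.testing.assert_allclose(back.values[~back.gap_mask],
                                   original.values[~original.gap_mask])


class TestReadOhioXml:
    def write_xml(self, tmp_path, body):
        path = tmp_path / "patient.xml"
        path.write_text(f'<patient id="559">{body}</patient>')
        return path

    def test_two_events_five_minutes_apart(self, tmp_path):
        path = self.write_xml(tmp_path, (
            '<glucose_level>'
            '<event ts="07-12-2021 01:17:00" value="101"/>'
            '<event ts="07-12-2021 01:22:00" value="98"/>'
            '</glucose_level>'))
        series = read_ohio_xml(path)
        assert len(series) == 2 and series.patient_id == "559"
        np.testing.assert_array_equal(series.values, [101, 98])

    def test_missing_glucose_channel_rejected(self, tmp_path):
        path = self.write_xml(tmp_path, (
            '<basal><event ts="07-12-2021 01:17:00" value="1.2"/></basal>'))
        with pytest.raises(ValueError, match="glucose_level"):
            read_ohio_xml(path)

    def test_ten_minute_step_leaves_gap(self, tmp_path):
        path = self.write_xml(tmp_path, (
            '<glucose_level>'
            '<event ts="07-12-2021 01:00:00" value="101"/>'
            '<event ts="07-12-2021 01:10:00" value="99"/>'
            '</glucose_level>'))
        series = read_ohio_xml(path)
        # grid reconstruction: 0, 5 (missing), 10 minutes
        assert len(series) == 3
        np.testing.assert_array_equal(series.gap_mask, [False, True, False])


# ---------------------------------------------------------------------------
# smoothing and rescaling
# ---------------------------------------------------------------------------

class TestSmooth:
    def test_window_one_is_identity(self):
        s = series_from_values([100, 400, 100])
        np.testing.assert_array_equal(smooth(s, 1).values, s.values)

    def test_median_removes_isolated_spike(self):
        s = series_from_values([100, 400, 100])
        out = smooth(s, 3)
        np.testing.assert_array_equal(out.values, [100, 100, 100])

    def test_constant_series_unchanged(self):
        s = series_from_values([120.0] * 10)
        np.testing.assert_array_equal(smooth(s, 3).values, s.values)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(series_from_values([100, 100]), 2)

    def test_gaps_excluded_and_preserved(self):
        s = series_from_values([100, np.nan, 300, 100, 100])
        out = smooth(s, 3)
        np.testing.assert_array_equal(out.gap_mask, s.gap_mask)
        # window at index 2 sees {300, 100} (gap excluded) -> median 200
        assert out.values[2] == 200.0


class TestRescale:
    def test_scaling_rule_example(self):
        s = series_from_values([130.6])
        scaled = rescale(s, 0.01)
        np.testing.assert_allclose(scaled.values, [1.306])
        assert scaled.scale == 0.01

    def test_factor_one_is_identity(self, segments10):
        out = rescale(segments10, 1.0)
        np.testing.assert_array_equal(out.inputs, segments10.inputs)

    def test_inverse_roundtrip_exact(self, segments10):
        back = rescale(rescale(segments10, 0.01), 100.0)
        np.testing.assert_allclose(back.inputs, segments10.inputs, rtol=1e-12)
        np.testing.assert_allclose(back.targets, segments10.targets, rtol=1e-12)

    def test_nonpositive_factor_rejected(self, segments10):
        with pytest.raises(ValueError):
            rescale(segments10, 0.0)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def brute_force_segment_count(gap_mask, n_in, h, stride):
    """Independent enumeration of valid (window, target) index pairs."""
    ok = ~np.asarray(gap_mask)
    count = 0
    for s in range(0, len(ok), stride):
        t = s + n_in - 1 + h
        if t >= len(ok):
            break
        if ok[s:s + n_in].all() and ok[t]:
            count += 1
    return count


class TestMakeSegments:
    def test_thirty_minute_window_has_seven_values(self):
        s = series_from_values([100.0] * 37)
        segs = make_segments(s, input_minutes=30, horizon_minutes=30)
        assert segs.window == 7

    def test_gap_free_count_matches_enumeration(self):
        s = series_from_values([100.0] * 37)
        segs = make_segments(s, input_minutes=30, horizon_minutes=30)
        assert len(segs) == 25

    def test_too_short_series_yields_empty_set(self):
        s = series_from_values([100.0] * 7)
        assert len(make_segments(s, horizon_minutes=30)) == 0

    def test_no_segment_contains_masked_sample(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(60, 200, 200)
        v[rng.uniform(size=200) < 0.15] = np.nan
        s = series_from_values(v)
        segs = make_segments(s, horizon_minutes=15)
        for i in range(len(segs)):
            start = segs.start_indices[i]
            assert not np.isnan(v[start:start + 7]).any()
            assert not np.isnan(v[start + 6 + 3])

    @settings(max_examples=25, deadline=None)
    @given(gaps=st.lists(st.booleans(), min_size=10, max_size=80),
           horizon=st.sampled_from([5, 15, 30, 60]),
           stride=st.sampled_from([5, 10]))
    def test_count_matches_brute_force_on_random_gap_patterns(self, gaps, horizon,
                                                              stride):
        gap = np.array(gaps)
        v = np.where(gap, np.nan, 120.0)
        s = series_from_values(v)
        segs = make_segments(s, horizon_minutes=horizon, stride_minutes=stride)
        assert len(segs) == brute_force_segment_count(gap, 7, horizon // 5,
                                                      stride // 5)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            make_segments(series_from_values([100.0] * 40), horizon_minutes=7)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

class TestLabels:
    @pytest.mark.parametrize("bg,expected", [
        (79, GlycemicLabel.HYPO), (79.999, GlycemicLabel.HYPO),
        (80, GlycemicLabel.NORMO), (180, GlycemicLabel.NORMO),
        (181, GlycemicLabel.HYPER),
    ])
    def test_three_class_boundaries(self, bg, expected):
        assert classify_bg([bg])[0] == expected

    def test_binary_positive_class_is_hypo(self):
        labels = classify_bg([79, 80, 200], scheme="binary")
        np.testing.assert_array_equal(
            labels, [BinaryLabel.HYPO, BinaryLabel.NO_HYPO, BinaryLabel.NO_HYPO])

    def test_labels_partition_segments(self, segments10):
        labeled = assign_labels(segments10, scheme="three_class")
        assert labeled.labels.shape == (10,)
        assert set(labeled.labels) <= {0, 1, 2}
        recomputed = classify_bg(labeled.targets_mgdl)
        np.testing.assert_array_equal(labeled.labels, recomputed)

    def test_thresholds_apply_to_unscaled_target(self, segments10):
        # segments are in 0.01 units; labels must still use mg/dL thresholds
        labeled = assign_labels(segments10, scheme="binary")
        expected = (segments10.targets / 0.01 < 80).astype(int)
        np.testing.assert_array_equal(labeled.labels, expected)


# ---------------------------------------------------------------------------
# splitting and duration arithmetic
# ---------------------------------------------------------------------------

class TestSplit:
    def make_chrono_segments(self, n=100):
        s = series_from_values([100.0] * (n + 12))
        return make_segments(s, horizon_minutes=30)

    def test_counts_and_no_window_overlap(self):
        segs = self.make_chrono_segments()
        train, test = split_target_patient(segs, 60)
        assert len(train) == 60
        assert len(test) <= 40
        assert test.start_indices.min() > train.target_indices.max()

    def test_n_train_zero_keeps_everything_for_test(self):
        segs = self.make_chrono_segments()
        train, test = split_target_patient(segs, 0)
        assert len(train) == 0 and len(test) == len(segs)

    def test_n_train_beyond_size_leaves_empty_test(self):
        segs = self.make_chrono_segments()
        train, test = split_target_patient(segs, 10_000)
        assert len(train) == len(segs) and len(test) == 0

    def test_thousand_segments_fit_in_83_hours_of_data(self):
        # 83 h of gap-free 5-min data: 997 samples
        n = 83 * 12 + 1
        segs = make_segments(series_from_values([100.0] * n), horizon_minutes=30)
        train, _ = split_target_patient(segs, 1000)
        assert len(train) >= 980  # 1000 windows span ~83 h minus edge effects

    def test_duration_arithmetic(self):
        assert segments_duration_hours(1000, 5) == 83
        assert segments_duration_hours(12, 5) == 1
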