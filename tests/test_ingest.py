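"""Ingestion: parsing, latching, trimming, window consolidation, CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wristmine as wm
from wristmine import ingest
from wristmine.ingest import (
    TIME_FEATURES,
    clean_and_trim,
    consolidate,
    instance_count,
    latch_to_fastest,
    read_feature_csv,
    read_raw,
    write_feature_csv,
)

from conftest import make_latched_records


def sparse_records(observations):
    """Raw rows with only the given (time, column, value) cells populated."""
    times = sorted({t for t, _, _ in observations})
    frame = pd.DataFrame({"unixtime": [float(t) for t in times]})
    for col in wm.RAW_COLUMNS[1:-2]:
        frame[col] = np.nan
    for t, col, value in observations:
        frame.loc[frame["unixtime"] == t, col] = value
    frame["activity"] = "homework"
    frame["alias"] = "ana"
    return frame[list(wm.RAW_COLUMNS)]


class TestReadRaw:
    def test_rejects_non_numeric_cell_naming_the_column(self, tmp_path):
        frame = make_latched_records(5)
        frame.loc[2, "hrRate"] = "seventy"
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="hrRate"):
            read_raw([path])

    def test_rejects_unknown_activity_label(self, tmp_path):
        frame = make_latched_records(5, activity="homework")
        frame["activity"] = "napping"
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="napping"):
            read_raw([path])

    def test_rejects_header_mismatch(self, tmp_path):
        frame = make_latched_records(5).rename(columns={"hrRate": "heartRate"})
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="header mismatch"):
            read_raw([path])

    def test_groups_by_activity_across_files(self, tmp_path):
        paths = []
        for i, label in enumerate(("exam", "eating", "reading")):
            frame = make_latched_records(10, activity=label, t0=1e9 + 10000 * i)
            p = tmp_path / f"{label}.csv"
            frame.to_csv(p, index=False)
            paths.append(p)
        records = read_raw(paths)
        assert set(records["activity"]) == {"exam", "eating", "reading"}
        assert records["unixtime"].is_monotonic_increasing


class TestLatch:
    def test_forward_fills_single_heart_rate_observation(self):
        obs = [(t, "gyroXAccel", 0.1) for t in range(5)] + [(0, "hrRate", 70.0)]
        latched = latch_to_fastest(sparse_records(obs))
        assert len(latched) == 5
        assert (latched["hrRate"] == 70.0).all()

    def test_step_counter_forward_fill_hand_trace(self):
        obs = [(t, "gyroXAccel", 0.1) for t in range(5)]
        obs += [(0, "pedTotalSteps", 100.0), (3, "pedTotalSteps", 120.0)]
        latched = latch_to_fastest(sparse_records(obs))
        assert latched["pedTotalSteps"].tolist() == [100.0, 100.0, 100.0, 120.0, 120.0]

    def test_constant_slow_channel_stays_constant(self):
        obs = [(t, "gyroXAccel", 0.1) for t in range(6)]
        obs += [(t, "tempSkin", 33.5) for t in (0, 3)]
        latched = latch_to_fastest(sparse_records(obs))
        assert (latched["tempSkin"] == 33.5).all()

    def test_is_idempotent(self, small_cohort):
        records, _ = small_cohort
        once = latch_to_fastest(records)
        twice = latch_to_fastest(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_backfills_head_with_warning(self):
        obs = [(t, "gyroXAccel", 0.1) for t in range(5)] + [(3, "hrRate", 64.0)]
        with pytest.warns(UserWarning, match="hrRate"):
            latched = latch_to_fastest(sparse_records(obs))
        assert (latched["hrRate"] == 64.0).all()

    def test_output_rows_are_gyro_ticks_only(self):
        obs = [(t, "gyroXAccel", 0.1) for t in (0, 1, 2)] + [(5, "hrRate", 70.0)]
        latched = latch_to_fastest(sparse_records(obs))
        assert latched["unixtime"].tolist() == [0.0, 1.0, 2.0]


class TestTrim:
    def test_caps_a_long_classroom_session_at_90_minutes(self):
        frame = make_latched_records(6000, activity="classroom-session")
        trimmed = clean_and_trim(frame, {"classroom-session": 5400})
        span = trimmed["unixtime"].max() - trimmed["unixtime"].min()
        assert span == 5400.0
        pd.testing.assert_frame_equal(trimmed, frame.iloc[:5401].reset_index(drop=True))

    def test_short_segment_is_unchanged(self):
        frame = make_latched_records(1000, activity="classroom-session")
        trimmed = clean_and_trim(frame, {"classroom-session": 5400})
        pd.testing.assert_frame_equal(trimmed, frame)

    def test_unmapped_activity_is_untouched(self):
        frame = make_latched_records(6000, activity="homework")
        trimmed = clean_and_trim(frame, {"classroom-session": 5400})
        pd.testing.assert_frame_equal(trimmed, frame)

    def test_negative_cap_is_rejected(self):
        frame = make_latched_records(10)
        with pytest.raises(ValueError, match="negative"):
            clean_and_trim(frame, {"homework": -1})


class TestConsolidate:
    def test_constant_heart_rate_passes_through(self):
        frame = make_latched_records(600, hrRate=70.0)
        rows = consolidate(frame)
        assert len(rows) == 2
        assert (rows["hrRate"] == 70.0).all()

    def test_step_deltas_telescope_to_the_counter_span(self):
        steps = np.linspace(0.0, 40.0, 300)
        frame = make_latched_records(300, pedTotalSteps=steps)
        rows = consolidate(frame)
        assert len(rows) == 1
        assert rows["pedTotalSteps"].iloc[0] == pytest.approx(
            steps[-1] - steps[0], abs=1e-12
        )

    def test_sum_of_squares_from_instance_means(self):
        frame = make_latched_records(300, accelX=1.0, accelY=2.0, accelZ=2.0)
        rows = consolidate(frame)
        assert rows["accelXYZ"].iloc[0] == pytest.approx(9.0, abs=1e-12)

    def test_non_monotone_counter_is_rejected(self):
        cal = np.linspace(0, 10, 300)
        cal[150] = 5.0
        cal[151] = 2.0  # drops
        frame = make_latched_records(300, cal=np.sort(cal)[::-1])
        with pytest.raises(ValueError, match="cal"):
            consolidate(frame)

    def test_empty_input_gives_empty_table_with_header(self):
        rows = consolidate(pd.DataFrame(columns=list(wm.RAW_COLUMNS)))
        assert rows.empty
        assert list(rows.columns) == ["unixtime", *TIME_FEATURES, "activity", "alias"]

    @given(duration=st.integers(min_value=2, max_value=4000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_instance_count_matches_closed_form(self, duration):
        frame = make_latched_records(duration)
        rows = consolidate(frame)
        span = duration - 1  # last minus first timestamp at 1 Hz
        assert len(rows) == instance_count(span, 300.0)

    def test_conservation_over_a_synthetic_segment(self, small_cohort):
        records, _ = small_cohort
        latched = latch_to_fastest(records)
        for seg in ingest.iter_segments(latched):
            t_rel = seg["unixtime"].to_numpy() - seg["unixtime"].iloc[0]
            keep, _, n_inst = ingest.window_indices(t_rel, 300.0)
            if n_inst == 0:
                continue
            kept = seg[keep]
            rows = consolidate(seg)
            for col in ("pedTotalSteps", "cal", "distTotal"):
                total = rows[col].sum()
                span = kept[col].iloc[-1] - kept[col].iloc[0]
                assert total == pytest.approx(span, abs=1e-6), col


class TestFeatureCsv:
    def test_round_trip_is_lossless(self, small_table, tmp_path):
        path = tmp_path / "features.csv"
        write_feature_csv(small_table, path)
        back = read_feature_csv(path)
        pd.testing.assert_frame_equal(back, small_table)

    def test_has_19_plus_36_plus_3_columns_with_wavelets(self, small_table):
        assert small_table.shape[1] == 19 + 36 + 3  # unixtime, activity, alias

    def test_header_mismatch_lists_unexpected_columns(self, small_table, tmp_path):
        bad = small_table.rename(columns={"hrRate": "bpm"})
        path = tmp_path / "features.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="bpm"):
            read_feature_csv(path)

    def test_empty_table_round_trips_header_only(self, tmp_path):
        empty = pd.DataFrame(columns=["unixtime", *TIME_FEATURES, "activity", "alias"])
        path = tmp_path / "empty.csv"
        write_feature_csv(empty, path)
        back = read_feature_csv(path)
        assert back.empty
        assert list(back.columns) == list(empty.columns)
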