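"""Synthetic stream generator: schedules, streams, raw-file round trips."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import wristmine as wm
from wristmine.ingest import read_raw
from wristmine.profiles import MotionSpectrum
from wristmine.synthetic import (
    DEFAULT_TZ,
    day_directory_name,
    expected_duration,
    sample_duration,
)

DATE = dt.date(2018, 5, 3)


def local_hour(ts: float) -> int:
    return dt.datetime.fromtimestamp(ts, DEFAULT_TZ).hour


@pytest.fixture()
def day_profiles(profiles):
    return [profiles[a] for a in ("sleeping", "eating", "transportation", "homework")]


class TestDaySchedule:
    def test_is_deterministic_for_a_fixed_seed(self, day_profiles):
        a = wm.generate_day_schedule(day_profiles, DATE, "ana", seed=5)
        b = wm.generate_day_schedule(day_profiles, DATE, "ana", seed=5)
        assert a == b

    def test_episodes_do_not_overlap_and_cover_requested_kinds(self, day_profiles):
        schedule = wm.generate_day_schedule(day_profiles, DATE, "ana", seed=1)
        for first, second in zip(schedule, schedule[1:]):
            assert first.end_unixtime <= second.start_unixtime
        labels = {ep.activity_label for ep in schedule}
        assert {"sleeping", "eating"} <= labels

    def test_planted_breakfast_starts_within_the_breakfast_hours(self, day_profiles):
        for seed in range(10):
            schedule = wm.generate_day_schedule(
                day_profiles, DATE, "ana", seed=seed, meals=("breakfast",)
            )
            eating = [ep for ep in schedule if ep.activity_label == "eating"]
            assert len(eating) == 1
            assert 4 <= local_hour(eating[0].start_unixtime) <= 9

    def test_empty_profile_list_is_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wm.generate_day_schedule([], DATE, "ana", seed=0)

    def test_infeasible_day_reports_the_overflow(self, profiles):
        import dataclasses

        def fixed(label, seconds):
            return dataclasses.replace(
                profiles[label],
                duration_mean_s=seconds,
                duration_sd_s=0.0,
                duration_min_s=seconds,
                duration_max_s=seconds,
            )

        # 30,000 + 40,000 + 18,000 s of requested activity cannot fit a day.
        many = [fixed("sleeping", 30000.0), fixed("job", 40000.0), fixed("homework", 18000.0)]
        with pytest.raises(ValueError, match="exceeds 24 h"):
            wm.generate_day_schedule(many, DATE, "ana", seed=0)

    def test_sleep_duration_sampler_recovers_its_mean(self, profiles):
        """Monte-Carlo check of the clipped sampler at the sleeping calibration."""
        rng = np.random.default_rng(2024)
        sleeping = profiles["sleeping"]
        durations = [sample_duration(sleeping, rng) for _ in range(200)]
        assert np.mean(durations) == pytest.approx(20925.5, rel=0.05)

    def test_analytic_expected_duration_matches_large_monte_carlo(self, profiles):
        rng = np.random.default_rng(9)
        for label in ("job", "sleeping", "eating"):
            p = profiles[label]
            draws = np.clip(
                rng.normal(p.duration_mean_s, p.duration_sd_s, 100_000),
                p.duration_min_s,
                p.duration_max_s,
            )
            assert expected_duration(p) == pytest.approx(draws.mean(), rel=0.01)


class TestStreams:
    def test_heart_rate_duty_cycle_on_fraction(self, profiles, sensor_config):
        ep = wm.ActivityEpisode("ana", "sleeping", 0.0, 400.0)
        rec = wm.synthesize_streams(ep, profiles["sleeping"], sensor_config, seed=0)
        hr = rec.dropna(subset=["hrRate"])
        per_period = hr.groupby((hr["unixtime"] // 40).astype(int)).size()
        # 12.5% of a 40 s period at 1 Hz -> 5 samples in every full period.
        expected = 0.125 * 40 * sensor_config.hr_rate_hz
        assert set(per_period) == {int(expected)}
        on_span = hr.groupby((hr["unixtime"] // 40).astype(int))["unixtime"].agg(np.ptp)
        assert (on_span <= 0.125 * 40).all()

    def test_sample_counts_match_duty_schedule(self, profiles, sensor_config):
        ep = wm.ActivityEpisode("ana", "homework", 0.0, 1000.0)
        rec = wm.synthesize_streams(ep, profiles["homework"], sensor_config, seed=1)
        n_periods = int(1000.0 // 40.0)
        gyro = rec.dropna(subset=["gyroXAccel"])
        per_on = int(round(0.05 * 40 * sensor_config.gyro_rate_hz))
        assert abs(len(gyro) - n_periods * per_on) <= per_on  # trailing partial period
        hr = rec.dropna(subset=["hrRate"])
        assert abs(len(hr) - n_periods * 5) <= 5

    def test_zero_noise_profile_yields_constant_heart_rate(self, profiles, sensor_config):
        import dataclasses

        quiet = dataclasses.replace(
            profiles["sleeping"], hr_sd_bpm=0.0, motion_spectrum=MotionSpectrum()
        )
        ep = wm.ActivityEpisode("ana", "sleeping", 0.0, 800.0)
        rec = wm.synthesize_streams(ep, quiet, sensor_config, seed=3)
        hr = rec["hrRate"].dropna()
        assert (hr == quiet.hr_mean_bpm).all()
        assert (rec["tempSkin"].dropna() == quiet.skin_temp_c).all()

    def test_running_heart_rate_recovers_profile_mean_over_an_hour(self, profiles):
        ep = wm.ActivityEpisode("ana", "running", 0.0, 3600.0)
        rec = wm.synthesize_streams(ep, profiles["running"], seed=11)
        assert rec["hrRate"].dropna().mean() == pytest.approx(76.6, abs=2.0)

    def test_cumulative_counters_never_decrease(self, profiles, sensor_config):
        for label in ("running", "job", "sleeping"):
            ep = wm.ActivityEpisode("ana", label, 0.0, 2000.0)
            rec = wm.synthesize_streams(ep, profiles[label], sensor_config, seed=7)
            for col in ("pedTotalSteps", "cal", "distTotal"):
                values = rec[col].dropna().to_numpy()
                assert np.all(np.diff(values) >= 0), (label, col)

    def test_calorie_totals_converge_to_the_profile_rate(self, profiles):
        rng = np.random.default_rng(31)
        prof = profiles["running"]
        rates = []
        for _ in range(200):
            d = max(sample_duration(prof, rng), 40.0)
            ep = wm.ActivityEpisode("ana", "running", 0.0, d)
            rec = wm.synthesize_streams(ep, prof, seed=rng)
            cal = rec[["unixtime", "cal"]].dropna()
            rates.append(cal["cal"].iloc[-1] / cal["unixtime"].iloc[-1])
        assert np.mean(rates) == pytest.approx(prof.calorie_rate_cal_per_s, rel=0.05)

    def test_short_episode_is_rejected(self, profiles, sensor_config):
        ep = wm.ActivityEpisode("ana", "eating", 0.0, 10.0)
        with pytest.raises(ValueError, match="duty"):
            wm.synthesize_streams(ep, profiles["eating"], sensor_config, seed=0)

    def test_records_carry_label_and_alias_and_are_sorted(self, profiles):
        ep = wm.ActivityEpisode("ana", "exam", 5000.0, 500.0)
        rec = wm.synthesize_streams(ep, profiles["exam"], seed=0)
        assert (rec["activity"] == "exam").all()
        assert (rec["alias"] == "ana").all()
        assert rec["unixtime"].is_monotonic_increasing
        assert rec["unixtime"].is_unique


class TestRawFiles:
    def test_day_directory_name_format(self):
        ts = dt.datetime(2018, 5, 3, 12, 0, tzinfo=DEFAULT_TZ).timestamp()
        assert day_directory_name(ts) == "03may2018"

    def test_paths_contain_day_alias_activity(self, profiles, tmp_path):
        start = dt.datetime(2018, 5, 3, 10, 0, tzinfo=DEFAULT_TZ).timestamp()
        ep = wm.ActivityEpisode("ana", "exam", start, 300.0)
        rec = wm.synthesize_streams(ep, profiles["exam"], seed=0)
        paths = wm.write_raw_files(rec, tmp_path)
        assert len(paths) == 1
        assert "03may2018" in str(paths[0])
        assert "ana" in str(paths[0])
        assert "exam" in str(paths[0])

    def test_empty_records_write_nothing(self, tmp_path):
        empty = pd.DataFrame(columns=list(wm.RAW_COLUMNS))
        assert wm.write_raw_files(empty, tmp_path) == []

    def test_round_trip_reproduces_records_exactly(self, profiles, tmp_path):
        start = dt.datetime(2018, 5, 4, 8, 0, tzinfo=DEFAULT_TZ).timestamp()
        frames = []
        for label, offset in (("eating", 0.0), ("homework", 4000.0)):
            ep = wm.ActivityEpisode("ana", label, start + offset, 600.0)
            frames.append(wm.synthesize_streams(ep, profiles[label], seed=2))
        records = pd.concat(frames, ignore_index=True).sort_values(
            "unixtime", ignore_index=True
        )
        paths = wm.write_raw_files(records, tmp_path)
        assert len(paths) == 2
        back = read_raw(sorted(paths))
        pd.testing.assert_frame_equal(
            back.sort_values("unixtime", ignore_index=True), records
        )
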