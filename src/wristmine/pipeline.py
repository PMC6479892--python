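"""End-to-end glue: simulate a cohort, run the full feature pipeline.

These helpers wire the stage modules together the way the command-line
interface and the acceptance experiments use them: day schedules to raw
streams, raw streams to latched/trimmed/consolidated instance rows, and the
per-window wavelet feature block appended to the time-domain features.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ingest
from .profiles import ActivityProfile, SensorConfig, load_profiles
from .synthetic import (
    DEFAULT_TZ,
    ActivityEpisode,
    generate_day_schedule,
    synthesize_streams,
)
from .wavelets import (
    DEFAULT_BUFFER,
    DEFAULT_LEVELS,
    WAVELET_CHANNELS,
    FilterPair,
    daubechies4_filters,
    wavelet_feature_row,
)


def simulate_cohort(
    profiles: Mapping[str, ActivityProfile] | None = None,
    aliases: Sequence[str] = ("ana", "beto"),
    n_days: int = 3,
    start_date: dt.date = dt.date(2018, 5, 3),
    config: SensorConfig | None = None,
    seed: int = 0,
    tz: dt.tzinfo = DEFAULT_TZ,
    activities_per_day: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[ActivityEpisode]]:
    """Simulate raw records for several aliases over several days.

    Returns the concatenated raw record table (sorted by time) and the
    ground-truth episode list. Randomness is split per (alias, day) from the
    one seed, so any sub-cohort is reproducible.
    """
    profiles = profiles or load_profiles()
    config = config or SensorConfig()
    frames: list[pd.DataFrame] = []
    episodes: list[ActivityEpisode] = []
    rotating = [
        a
        for a in (
            "classroom-session",
            "homework",
            "exam",
            "job",
            "running",
            "watching TV-Series",
            "reading",
        )
        if a in profiles
    ]
    for a_idx, alias in enumerate(aliases):
        for d in range(n_days):
            if activities_per_day is not None:
                labels = list(activities_per_day)
            else:
                # A realistic day: sleep, meals, transport, three rotating
                # daytime activities (all ten covered across a cohort).
                labels = [a for a in ("sleeping", "eating", "transportation") if a in profiles]
                if rotating:
                    labels += [
                        rotating[(3 * (a_idx + d) + k) % len(rotating)] for k in range(3)
                    ]
            day_profiles = [profiles[a] for a in dict.fromkeys(labels)]
            date = start_date + dt.timedelta(days=d)
            day_eps = None
            for attempt in range(20):
                child = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(a_idx, d, attempt))
                )
                try:
                    day_eps = generate_day_schedule(day_profiles, date, alias, child, tz=tz)
                    break
                except ValueError:
                    continue
            if day_eps is None:
                raise ValueError(
                    f"could not draw a feasible schedule for {alias} on {date}"
                )
            for ep in day_eps:
                if ep.duration_s < config.duty_period_s:
                    continue
                episodes.append(ep)
                frames.append(
                    synthesize_streams(ep, profiles[ep.activity_label], config, child)
                )
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values("unixtime", kind="stable", ignore_index=True)
    return records, episodes


def extract_wavelet_features(
    latched: pd.DataFrame,
    instance_window_s: float = 300.0,
    min_fill: float = 0.5,
    gap_s: float = ingest.SEGMENT_GAP_S,
    filters: FilterPair | None = None,
    buffer: int = DEFAULT_BUFFER,
    levels: int = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Compute the 36 subband-energy features per instance window.

    Windows are carved exactly as :func:`wristmine.ingest.consolidate` carves
    them, so the resulting rows join the time-domain instance rows one-to-one
    on (alias, activity, window-start unixtime).
    """
    filters = filters or daubechies4_filters()
    rows: list[dict] = []
    for seg in ingest.iter_segments(latched, gap_s):
        t = seg["unixtime"].to_numpy(float)
        t_rel = t - t[0]
        keep, inst_idx, n_inst = ingest.window_indices(t_rel, instance_window_s, min_fill)
        if n_inst == 0:
            continue
        seg = seg[keep]
        for i in range(n_inst):
            window = seg[inst_idx == i]
            if len(window) < 2:
                continue
            channels = {c: window[c].to_numpy(float) for c in WAVELET_CHANNELS}
            row = wavelet_feature_row(channels, filters, n=buffer, levels=levels)
            row["unixtime"] = t[0] + i * instance_window_s
            row["activity"] = seg["activity"].iloc[0]
            row["alias"] = seg["alias"].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)


def extract_features(
    records: pd.DataFrame,
    subwindow_s: float = 5.0,
    instance_window_s: float = 300.0,
    min_fill: float = 0.5,
    trim: Mapping[str, float] | None = None,
    wavelet: bool = True,
    filters: FilterPair | None = None,
) -> pd.DataFrame:
    """Raw records to the full labeled feature table.

    Latches to the gyroscope grid, optionally trims over-long segments,
    consolidates into instance rows, and (by default) appends the wavelet
    feature block.
    """
    latched = ingest.latch_to_fastest(records)
    if trim:
        latched = ingest.clean_and_trim(latched, trim)
    table = ingest.consolidate(latched, subwindow_s, instance_window_s, min_fill)
    if not wavelet or table.empty:
        return table
    wl = extract_wavelet_features(
        latched, instance_window_s, min_fill, filters=filters
    )
    merged = table.merge(wl, on=["unixtime", "activity", "alias"], how="inner")
    return merged
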