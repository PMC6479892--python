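"""Raw-stream ingestion, multi-rate alignment and window consolidation.

The stages mirror how duty-cycled wearable data becomes a classification
table: parse the raw per-(day, alias, activity) CSVs, latch slow sensors to
the gyroscope tick grid (forward fill, no interpolation), trim over-long
labeled segments, and consolidate each segment into fixed-length instance
rows (default 5 min, built from 5 s sub-windows) carrying the 19 time-domain
features.

Instantaneous channels (accelerometer, gyroscope, speed, pace, heart rate,
skin temperature) consolidate by averaging; cumulative counters (steps,
calories, total distance) consolidate by telescoping deltas, so summed
instance deltas conserve the raw counter span exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .profiles import ACTIVITIES
from .synthetic import RAW_COLUMNS, SENSOR_COLUMNS

#: The 19 time-domain classification features, in table order.
TIME_FEATURES: tuple[str, ...] = (
    "accelX",
    "accelY",
    "accelZ",
    "accelXYZ",
    "distSpeed",
    "distPace",
    "distTotal",
    "gyroXAccel",
    "gyroYAccel",
    "gyroZAccel",
    "gyroXYZAccel",
    "gyroXAnguVel",
    "gyroYAnguVel",
    "gyroZAnguVel",
    "gyroXYZAnguVel",
    "hrRate",
    "tempSkin",
    "pedTotalSteps",
    "cal",
)

#: Channels whose windowed value is the difference of end and start readings.
CUMULATIVE_CHANNELS: tuple[str, ...] = ("pedTotalSteps", "cal", "distTotal")

#: Observed channels consolidated by averaging (sum-of-squares channels are
#: recomputed from instance-level means, so they are not listed here).
INSTANT_CHANNELS: tuple[str, ...] = tuple(
    c for c in SENSOR_COLUMNS if c not in CUMULATIVE_CHANNELS
)

GYRO_CHANNELS: tuple[str, ...] = (
    "gyroXAccel",
    "gyroYAccel",
    "gyroZAccel",
    "gyroXAnguVel",
    "gyroYAnguVel",
    "gyroZAnguVel",
)

#: A gap longer than this (seconds) splits two same-labeled runs into
#: separate episodes/segments; must exceed the duty period's off phase.
SEGMENT_GAP_S = 600.0

_SUM_SQUARES = {
    "accelXYZ": ("accelX", "accelY", "accelZ"),
    "gyroXYZAccel": ("gyroXAccel", "gyroYAccel", "gyroZAccel"),
    "gyroXYZAnguVel": ("gyroXAnguVel", "gyroYAnguVel", "gyroZAnguVel"),
}


def read_raw(paths: Iterable[str | Path]) -> pd.DataFrame:
    """Parse raw CSV files into one timestamp-ordered record table.

    Empty cells stay missing (NaN). Malformed numeric cells and unknown
    activity labels raise with the offending file and column named.
    """
    frames = []
    for path in paths:
        path = Path(path)
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        extra = [c for c in raw.columns if c not in RAW_COLUMNS]
        missing = [c for c in RAW_COLUMNS if c not in raw.columns]
        if extra or missing:
            raise ValueError(
                f"{path}: raw header mismatch (unexpected {extra}, missing {missing})"
            )
        out = pd.DataFrame()
        for col in ("unixtime", *SENSOR_COLUMNS):
            cells = raw[col].replace("", np.nan)
            try:
                out[col] = pd.to_numeric(cells)
            except (ValueError, TypeError) as err:
                raise ValueError(f"{path}: non-numeric value in column {col!r}") from err
        bad = set(raw["activity"]) - set(ACTIVITIES)
        if bad:
            raise ValueError(f"{path}: unknown activity labels {sorted(bad)}")
        out["activity"] = raw["activity"]
        out["alias"] = raw["alias"]
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=list(RAW_COLUMNS))
    records = pd.concat(frames, ignore_index=True)
    return records.sort_values("unixtime", kind="stable", ignore_index=True)


def iter_segments(
    records: pd.DataFrame, gap_s: float = SEGMENT_GAP_S
) -> Iterator[pd.DataFrame]:
    """Yield contiguous (alias, activity) runs, split at gaps > ``gap_s``."""
    if records.empty:
        return
    for _, group in records.groupby("alias", sort=True):
        group = group.sort_values("unixtime", kind="stable")
        t = group["unixtime"].to_numpy()
        label_change = group["activity"].ne(group["activity"].shift()).to_numpy()
        gap = np.concatenate([[True], np.diff(t) > gap_s])
        seg_id = np.cumsum(label_change | gap)
        for _, seg in group.groupby(seg_id, sort=True):
            yield seg.reset_index(drop=True)


def latch_to_fastest(records: pd.DataFrame, gap_s: float = SEGMENT_GAP_S) -> pd.DataFrame:
    """Align slow sensors to the gyroscope ticks by forward fill (latching).

    Returns one fully-populated row per gyroscope tick within each segment.
    A channel first observed after a segment's first gyro tick is back-filled
    from its first observation, with a warning.
    """
    if records.empty:
        return records.copy()
    pieces = []
    for seg in iter_segments(records, gap_s):
        gyro_tick = seg[list(GYRO_CHANNELS)].notna().any(axis=1)
        filled = seg.copy()
        filled[list(SENSOR_COLUMNS)] = filled[list(SENSOR_COLUMNS)].ffill()
        head_nan = filled.loc[gyro_tick, list(SENSOR_COLUMNS)].isna().any(axis=0)
        if head_nan.any():
            warnings.warn(
                "back-filling channels first observed after the first gyro tick: "
                f"{sorted(head_nan[head_nan].index)}",
                stacklevel=2,
            )
            filled[list(SENSOR_COLUMNS)] = filled[list(SENSOR_COLUMNS)].bfill()
        pieces.append(filled.loc[gyro_tick])
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values("unixtime", kind="stable", ignore_index=True)


def clean_and_trim(
    records: pd.DataFrame,
    max_duration_by_activity: Mapping[str, float] | None = None,
    gap_s: float = SEGMENT_GAP_S,
) -> pd.DataFrame:
    """Drop the tail of any labeled segment beyond its activity's maximum.

    ``max_duration_by_activity`` maps labels to caps in seconds (e.g.
    classroom-session -> 5400); activities absent from the mapping are
    untouched. Kept samples are never altered.
    """
    caps = dict(max_duration_by_activity or {})
    for label, cap in caps.items():
        if cap < 0:
            raise ValueError(f"negative maximum duration for {label!r}: {cap}")
    if records.empty or not caps:
        return records.copy()
    pieces = []
    for seg in iter_segments(records, gap_s):
        cap = caps.get(seg["activity"].iloc[0])
        if cap is not None:
            t0 = seg["unixtime"].iloc[0]
            seg = seg[seg["unixtime"] - t0 <= cap]
        pieces.append(seg)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values("unixtime", kind="stable", ignore_index=True)


def instance_count(duration_s: float, window_s: float, min_fill: float = 0.5) -> int:
    """Closed-form number of instance windows covering a segment span."""
    n_full = int(duration_s // window_s)
    remainder = duration_s - n_full * window_s
    return n_full + (1 if remainder >= min_fill * window_s else 0)


def window_indices(
    t_rel: np.ndarray, window_s: float, min_fill: float = 0.5
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map segment-relative times to instance windows.

    Returns ``(keep, inst_idx, n_inst)``: which samples fall inside a kept
    window, each kept sample's window index, and the window count (per the
    closed form in :func:`instance_count`). A trailing partial window is
    dropped entirely when under ``min_fill`` full.
    """
    n_inst = instance_count(t_rel[-1], window_s, min_fill)
    raw_idx = (t_rel // window_s).astype(int)
    keep = raw_idx < n_inst
    return keep, raw_idx[keep], n_inst


def _consolidate_segment(
    seg: pd.DataFrame, subwindow_s: float, window_s: float, min_fill: float
) -> pd.DataFrame:
    t = seg["unixtime"].to_numpy(float)
    t_rel = t - t[0]
    keep, inst_idx, n_inst = window_indices(t_rel, window_s, min_fill)
    if n_inst == 0:
        return pd.DataFrame()
    if not keep.all():
        seg, t_rel = seg[keep], t_rel[keep]

    for col in CUMULATIVE_CHANNELS:
        v = seg[col].to_numpy(float)
        if np.any(np.diff(v) < -1e-9):
            raise ValueError(f"non-monotone cumulative counter {col!r} within a segment")

    sub_idx = (t_rel // subwindow_s).astype(int)
    sub = pd.DataFrame({"_sub": sub_idx, "_inst": inst_idx})
    for col in (*INSTANT_CHANNELS, *CUMULATIVE_CHANNELS):
        sub[col] = seg[col].to_numpy(float)

    grouped = sub.groupby("_sub", sort=True)
    inst_of_sub = grouped["_inst"].first()
    sub_means = grouped[list(INSTANT_CHANNELS)].mean()
    sub_last = grouped[list(CUMULATIVE_CHANNELS)].last()
    # Telescoping deltas: each sub-window closes against the previous
    # sub-window's last reading (segment start for the first one).
    first_row = seg[list(CUMULATIVE_CHANNELS)].iloc[0].astype(float)
    sub_deltas = sub_last.diff()
    sub_deltas.iloc[0] = sub_last.iloc[0] - first_row

    inst_means = sub_means.groupby(inst_of_sub).mean()
    inst_deltas = sub_deltas.groupby(inst_of_sub).sum()

    rows = pd.DataFrame(index=inst_means.index)
    rows["unixtime"] = t[0] + rows.index.to_numpy() * window_s
    for col in INSTANT_CHANNELS:
        rows[col] = inst_means[col]
    for col in CUMULATIVE_CHANNELS:
        rows[col] = inst_deltas[col]
    for name, (cx, cy, cz) in _SUM_SQUARES.items():
        rows[name] = rows[cx] ** 2 + rows[cy] ** 2 + rows[cz] ** 2
    rows["activity"] = seg["activity"].iloc[0]
    rows["alias"] = seg["alias"].iloc[0]
    return rows.reset_index(drop=True)


def consolidate(
    records: pd.DataFrame,
    subwindow_s: float = 5.0,
    instance_window_s: float = 300.0,
    min_fill: float = 0.5,
    gap_s: float = SEGMENT_GAP_S,
) -> pd.DataFrame:
    """Consolidate latched records into labeled instance rows.

    Two-level scheme: per ``subwindow_s`` sub-window, instantaneous channels
    average and cumulative channels take telescoping deltas; per
    ``instance_window_s`` instance, instantaneous features are the mean of
    sub-window means and differential features the sum of sub-window deltas.
    Sum-of-squares features are recomputed from instance-level channel means.
    A trailing partial window is kept iff at least ``min_fill`` full.
    """
    if records.empty:
        return pd.DataFrame(columns=["unixtime", *TIME_FEATURES, "activity", "alias"])
    pieces = [
        _consolidate_segment(seg, subwindow_s, instance_window_s, min_fill)
        for seg in iter_segments(records, gap_s)
    ]
    pieces = [p for p in pieces if not p.empty]
    if not pieces:
        return pd.DataFrame(columns=["unixtime", *TIME_FEATURES, "activity", "alias"])
    out = pd.concat(pieces, ignore_index=True)
    out = out.sort_values(["alias", "unixtime"], kind="stable", ignore_index=True)
    return out[["unixtime", *TIME_FEATURES, "activity", "alias"]]


def write_feature_csv(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the consolidated feature table; lossless float round trip."""
    rows.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating the header against the known names."""
    from .wavelets import WAVELET_FEATURES

    table = pd.read_csv(path)
    allowed = {"unixtime", *TIME_FEATURES, *WAVELET_FEATURES, "activity", "alias"}
    unexpected = [c for c in table.columns if c not in allowed]
    if unexpected:
        raise ValueError(f"{path}: unexpected feature columns {unexpected}")
    required = [c for c in ("unixtime", *TIME_FEATURES, "activity", "alias") if c not in table.columns]
    if required:
        raise ValueError(f"{path}: missing required columns {required}")
    present_wavelet = [c for c in WAVELET_FEATURES if c in table.columns]
    if present_wavelet and len(present_wavelet) != len(WAVELET_FEATURES):
        missing_w = [c for c in WAVELET_FEATURES if c not in table.columns]
        raise ValueError(f"{path}: incomplete wavelet feature block, missing {missing_w}")
    return table
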