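"""Descriptive habit analytics over the consolidated activity data.

Per-activity summary statistics (duration, calories, distance, speed, heart
rate), mean calorie-burn rates, meal classification by local start hour
(breakfast 4-9, lunch 10-17, dinner 18-23, inclusive integer hours; hours
0-3 stay unclassified), and age-based heart-rate intensity zones
(maximum heart rate = 220 - age).

Summary statistics are computed over reconstructed episodes (contiguous
alias/activity runs of instance rows), matching how per-activity durations
are reported; the standard deviation uses the population form, so an
activity observed once has sd exactly 0.
"""

from __future__ import annotations

import datetime as dt
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_TZ

#: Inclusive local-hour windows for meal classification.
MEAL_HOURS: dict[str, tuple[int, int]] = {
    "breakfast": (4, 9),
    "lunch": (10, 17),
    "dinner": (18, 23),
}

_STATS = ("avg", "min", "max", "sd")


class MealCounts(NamedTuple):
    breakfasts: int
    lunches: int
    dinners: int
    unclassified: int

    @property
    def total(self) -> int:
        return sum(self)


def episodes_from_instances(
    instances: pd.DataFrame, window_s: float = 300.0, gap_s: float = 600.0
) -> pd.DataFrame:
    """Reconstruct per-episode records from contiguous instance-row runs.

    Consecutive rows of one alias with the same activity label belong to one
    episode unless separated by more than ``gap_s`` beyond the window length.
    Episode duration counts each instance window in full; calories, distance
    and steps sum the differential features; heart rate and speed average
    the instantaneous ones.
    """
    if instances.empty:
        return pd.DataFrame(
            columns=[
                "alias",
                "activity",
                "start_unixtime",
                "duration_s",
                "calories",
                "distance_m",
                "steps",
                "hr_mean_bpm",
                "speed_mean_mps",
            ]
        )
    episodes = []
    for _, group in instances.groupby("alias", sort=True):
        group = group.sort_values("unixtime", kind="stable")
        t = group["unixtime"].to_numpy(float)
        new_run = group["activity"].ne(group["activity"].shift()).to_numpy()
        new_run |= np.concatenate([[True], np.diff(t) > window_s + gap_s])
        run_id = np.cumsum(new_run)
        for _, run in group.groupby(run_id, sort=True):
            episodes.append(
                {
                    "alias": run["alias"].iloc[0],
                    "activity": run["activity"].iloc[0],
                    "start_unixtime": run["unixtime"].iloc[0],
                    "duration_s": len(run) * window_s,
                    "calories": run["cal"].sum(),
                    "distance_m": run["distTotal"].sum(),
                    "steps": run["pedTotalSteps"].sum(),
                    "hr_mean_bpm": run["hrRate"].mean(),
                    "speed_mean_mps": run["distSpeed"].mean(),
                }
            )
    return pd.DataFrame(episodes)


def activity_summary(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-activity summary block over episode records.

    Returns one row per activity present in the data, with avg/min/max/sd
    (population sd) for duration, calories, distance, speed and heart rate,
    plus calorie rates in cal/s and cal/h and the episode count.
    """
    if episodes.empty:
        return pd.DataFrame()
    rows = {}
    blocks = {
        "duration": "duration_s",
        "calories": "calories",
        "distance": "distance_m",
        "speed": "speed_mean_mps",
        "hr": "hr_mean_bpm",
    }
    for activity, group in episodes.groupby("activity", sort=True):
        row: dict[str, float] = {}
        for block, col in blocks.items():
            v = group[col].to_numpy(float)
            row[f"{block}_avg"] = v.mean()
            row[f"{block}_min"] = v.min()
            row[f"{block}_max"] = v.max()
            row[f"{block}_sd"] = v.std(ddof=0)
        rate_s, rate_h = calorie_rate(row["calories_avg"], row["duration_avg"])
        row["rate_cal_s"] = rate_s
        row["rate_cal_h"] = rate_h
        row["n_episodes"] = len(group)
        rows[activity] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "activity"
    return out


def calorie_rate(mean_calories: float, mean_duration_s: float) -> tuple[float, float]:
    """Mean calorie-burn rate as (cal/s, cal/h); reports round to 2/1 decimals."""
    if mean_duration_s <= 0:
        raise ValueError(f"mean duration must be > 0, got {mean_duration_s}")
    rate_s = mean_calories / mean_duration_s
    return rate_s, rate_s * 3600.0


def classify_meal(timestamp: float, tz: dt.tzinfo = DEFAULT_TZ) -> str:
    """Classify a feeding timestamp by its local integer hour.

    Breakfast for hours 4-9, lunch 10-17, dinner 18-23 (bounds inclusive);
    anything else (hours 0-3) is "unclassified".
    """
    hour = dt.datetime.fromtimestamp(timestamp, tz).hour
    for meal, (lo, hi) in MEAL_HOURS.items():
        if lo <= hour <= hi:
            return meal
    return "unclassified"


def count_meals(
    eating_start_times: Sequence[float], tz: dt.tzinfo = DEFAULT_TZ
) -> MealCounts:
    """Count breakfasts/lunches/dinners among eating episodes by start time."""
    tally = {"breakfast": 0, "lunch": 0, "dinner": 0, "unclassified": 0}
    for ts in eating_start_times:
        tally[classify_meal(ts, tz)] += 1
    return MealCounts(
        tally["breakfast"], tally["lunch"], tally["dinner"], tally["unclassified"]
    )


def hr_zone(age: float, lo_frac: float, hi_frac: float) -> tuple[float, float]:
    """Heart-rate intensity zone bounds from the 220-minus-age maximum.

    E.g. a 50-70% moderate zone at age 23: maximum heart rate 197 bpm, lower
    bound 98.5 bpm, upper bound 137.9 bpm.
    """
    if not 0 < age < 120:
        raise ValueError(f"age must lie in (0, 120), got {age}")
    if not 0 < lo_frac <= hi_frac <= 1:
        raise ValueError(f"need 0 < lo_frac <= hi_frac <= 1, got {lo_frac}, {hi_frac}")
    mhr = 220.0 - age
    return lo_frac * mhr, hi_frac * mhr


def habit_report(
    summaries: pd.DataFrame,
    meal_counts: MealCounts | None = None,
    zone: tuple[float, float] | None = None,
    sleep_goal_h: float = 8.0,
    hr_proximity_bpm: float = 2.0,
) -> dict:
    """Deterministic JSON-ready habit report with anomaly flags.

    Flags sleep under the recommended nightly hours and any activity whose
    minimum or mean heart rate comes within ``hr_proximity_bpm`` of the
    sleeping mean (a possible drowsiness signal).
    """
    report: dict = {"activities": {}, "flags": []}
    for activity, row in summaries.iterrows():
        report["activities"][activity] = {
            "duration_h": round(row["duration_avg"] / 3600.0, 1),
            "duration_s": round(row["duration_avg"], 1),
            "rate_cal_s": round(row["rate_cal_s"], 2),
            "rate_cal_h": round(row["rate_cal_h"], 1),
            "hr_avg_bpm": round(row["hr_avg"], 1),
            "n_episodes": int(row["n_episodes"]),
        }
    if "sleeping" in summaries.index:
        sleep_h = summaries.loc["sleeping", "duration_avg"] / 3600.0
        if sleep_h < sleep_goal_h:
            report["flags"].append(
                f"sleeping averages {sleep_h:.1f} h, under the {sleep_goal_h:.0f} h recommendation"
            )
        sleep_hr = summaries.loc["sleeping", "hr_avg"]
        for activity, row in summaries.iterrows():
            if activity == "sleeping":
                continue
            for stat in ("hr_min", "hr_avg"):
                if abs(row[stat] - sleep_hr) <= hr_proximity_bpm:
                    report["flags"].append(
                        f"{activity} {stat.replace('hr_', '')} heart rate "
                        f"{row[stat]:.1f} bpm is within {hr_proximity_bpm:.0f} bpm "
                        f"of the sleeping average ({sleep_hr:.1f} bpm)"
                    )
                    break
    if meal_counts is not None:
        report["meals"] = {
            "breakfasts": meal_counts.breakfasts,
            "lunches": meal_counts.lunches,
            "dinners": meal_counts.dinners,
            "unclassified": meal_counts.unclassified,
            "per_category_if_balanced": round(meal_counts.total / 3.0, 1),
        }
    if zone is not None:
        report["hr_zone_bpm"] = [round(zone[0], 1), round(zone[1], 1)]
    return report
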