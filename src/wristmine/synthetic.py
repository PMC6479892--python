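"""Synthetic wrist-sensor stream generator.

Produces labeled raw sensor records with the statistical structure the
downstream analysis assumes: a day schedule of non-overlapping activity
episodes (sleep at night, meals inside the breakfast/lunch/dinner hour
windows, configurable daytime activities), duty-cycled multi-rate sensor
streams per episode, and the on-disk raw-file layout
``ddmonthyyyy/alias/activity.csv``.

All randomness flows from one explicit seed through a splittable
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import ACTIVITIES, ActivityProfile, SensorConfig

#: Column order of the raw CSV dialect. ``unixtime`` is POSIX seconds (with a
#: fractional part at sub-second sensor rates); duty-off / slow-sensor cells
#: are empty.
RAW_COLUMNS: tuple[str, ...] = (
    "unixtime",
    "accelX",
    "accelY",
    "accelZ",
    "gyroXAccel",
    "gyroYAccel",
    "gyroZAccel",
    "gyroXAnguVel",
    "gyroYAnguVel",
    "gyroZAnguVel",
    "hrRate",
    "tempSkin",
    "pedTotalSteps",
    "cal",
    "distTotal",
    "distSpeed",
    "distPace",
    "activity",
    "alias",
)

SENSOR_COLUMNS: tuple[str, ...] = RAW_COLUMNS[1:-2]

#: Fixed UTC-6 offset (Mexico City standard time); any tzinfo may be passed
#: instead wherever local clock time matters.
DEFAULT_TZ = dt.timezone(dt.timedelta(hours=-6), "UTC-6")

#: Local start-hour windows used when planting meals in a day schedule; each
#: lies strictly inside the corresponding meal-classification hour range.
MEAL_WINDOWS: Mapping[str, tuple[float, float]] = {
    "breakfast": (6.5, 8.5),
    "lunch": (12.0, 15.5),
    "dinner": (19.0, 21.5),
}

#: Gravity offset applied to the accelerometer z axis, m/s^2.
GRAVITY_M_PER_S2 = 9.81

#: Lag-one autocorrelation of the simulated heart-rate path.
HR_AR1_PHI = 0.9

#: Per-episode multiplicative jitter (sd) on the calorie rate, clipped at 0.1.
RATE_JITTER_SD = 0.25

#: Log-sd of the unit-mean lognormal per-episode factor on behavioural rates
#: (steps, distance, speed): published per-activity spreads for these
#: quantities are of the order of their means.
BEHAVIOUR_JITTER_LOG_SD = 0.7

#: Per-episode motion-intensity scaling (sd of a unit-mean factor): people do
#: not repeat an activity at identical vigour.
MOTION_JITTER_SD = 0.3

#: Skin-temperature variability: per-sample sensor noise and a slow
#: per-episode baseline offset (deg C).
TEMP_NOISE_SD = 0.8
TEMP_EPISODE_SD = 0.3

#: Per-episode heart-rate baseline offset (bpm) on top of the AR(1) path.
HR_EPISODE_SD = 0.75

#: Within-episode behavioural drift: log-scale sd of the slow (per duty
#: period) AR(1) modulation of step/distance rates — activity happens in
#: bouts, so consecutive windows of one episode differ in intensity.
BEHAVIOUR_DRIFT_LOG_SD = 0.5
#: Same, for the calorie rate (metabolic output drifts less than movement).
CALORIE_DRIFT_LOG_SD = 0.2
#: Same, for the motion-oscillation amplitude envelope.
MOTION_DRIFT_LOG_SD = 0.4
#: Per-period lag-one autocorrelation of the drift processes.
DRIFT_PHI = 0.85


@dataclass(frozen=True)
class ActivityEpisode:
    """One contiguous labeled activity bout of one alias."""

    alias: str
    activity_label: str
    start_unixtime: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("episode duration must be > 0")
        if self.activity_label not in ACTIVITIES:
            raise ValueError(f"unknown activity label: {self.activity_label!r}")

    @property
    def end_unixtime(self) -> float:
        return self.start_unixtime + self.duration_s


def sample_duration(profile: ActivityProfile, rng: np.random.Generator) -> float:
    """Draw one episode duration: normal(mean, sd) clipped to [min, max]."""
    if profile.duration_sd_s == 0:
        return profile.duration_mean_s
    raw = rng.normal(profile.duration_mean_s, profile.duration_sd_s)
    return float(np.clip(raw, profile.duration_min_s, profile.duration_max_s))


def expected_duration(profile: ActivityProfile) -> float:
    """Analytic mean of the clipped-normal duration sampler.

    For tight bounds this is close to ``duration_mean_s``; for activities
    whose sd rivals the mean the clipping shifts the effective mean, and this
    closed form is the generator's true setting.
    """
    from scipy.stats import norm

    mu, sd = profile.duration_mean_s, profile.duration_sd_s
    lo, hi = profile.duration_min_s, profile.duration_max_s
    if sd == 0:
        return mu
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + sd * (norm.pdf(a) - norm.pdf(b))
    )


def generate_day_schedule(
    profiles: Sequence[ActivityProfile],
    date: dt.date,
    alias: str,
    seed: int | np.random.Generator,
    tz: dt.tzinfo = DEFAULT_TZ,
    meals: Sequence[str] = ("breakfast", "lunch", "dinner"),
) -> list[ActivityEpisode]:
    """Plan one alias-day as a non-overlapping episode sequence.

    Sleep (if a sleeping profile is given) starts shortly after local
    midnight; each requested meal becomes an eating episode whose start hour
    falls inside its meal window; remaining profiles are placed once each, in
    order, into the free daytime gaps (their sampled durations truncated to
    fit). Deterministic for a fixed seed.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    unknown = [m for m in meals if m not in MEAL_WINDOWS]
    if unknown:
        raise ValueError(f"unknown meal names: {unknown}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    by_label: dict[str, ActivityProfile] = {}
    order: list[str] = []
    for p in profiles:
        if p.activity_label not in by_label:
            order.append(p.activity_label)
        by_label[p.activity_label] = p

    day_start = dt.datetime.combine(date, dt.time(0), tzinfo=tz).timestamp()
    day_end = day_start + 86400.0

    sleep_p = by_label.get("sleeping")
    eat_p = by_label.get("eating")
    others = [by_label[a] for a in order if a not in ("sleeping", "eating")]

    # Feasibility: the total requested time must fit in one day.
    total = sum(sample_duration(by_label[a], rng) for a in order)
    if eat_p is not None and len(meals) > 1:
        total += sum(sample_duration(eat_p, rng) for _ in range(len(meals) - 1))
    if total > 86400.0:
        raise ValueError(
            f"infeasible day: requested activity time {total:.0f} s exceeds 24 h "
            f"by {total - 86400.0:.0f} s"
        )

    episodes: list[ActivityEpisode] = []

    sleep_end = day_start
    if sleep_p is not None:
        s0 = day_start + float(rng.uniform(0.0, 1800.0))
        sdur = sample_duration(sleep_p, rng)
        sleep_end = s0 + sdur
        episodes.append(ActivityEpisode(alias, "sleeping", s0, sdur))

    # Meals are anchors; sleep is truncated if it would overrun breakfast.
    anchors: list[ActivityEpisode] = []
    if eat_p is not None:
        for meal in meals:
            lo, hi = MEAL_WINDOWS[meal]
            start = day_start + float(rng.uniform(lo, hi)) * 3600.0
            dur = min(sample_duration(eat_p, rng), 3600.0)
            if episodes and start < episodes[0].end_unixtime + 60.0:
                trunc = start - 60.0 - episodes[0].start_unixtime
                if trunc <= 0:
                    raise ValueError("infeasible day: sleep leaves no room for breakfast")
                episodes[0] = ActivityEpisode(
                    alias, "sleeping", episodes[0].start_unixtime, trunc
                )
            anchors.append(ActivityEpisode(alias, "eating", start, dur))
    episodes.extend(anchors)
    episodes.sort(key=lambda e: e.start_unixtime)

    # Fill free gaps with the remaining profiles, one episode each, in order.
    def gaps() -> list[tuple[float, float]]:
        out = []
        cursor = day_start
        for ep in sorted(episodes, key=lambda e: e.start_unixtime):
            if ep.start_unixtime - cursor > 900.0:
                out.append((cursor, ep.start_unixtime))
            cursor = max(cursor, ep.end_unixtime)
        if day_end - cursor > 900.0:
            out.append((cursor, day_end))
        return out

    pending = list(others)
    for gap_start, gap_end in gaps():
        cursor = gap_start
        while pending and gap_end - cursor > 900.0:
            prof = pending[0]
            start = cursor + float(rng.uniform(120.0, 600.0))
            room = gap_end - start - 60.0
            if room < 600.0:
                break
            dur = min(sample_duration(prof, rng), room)
            if dur < prof.duration_min_s and dur < room:
                break
            episodes.append(ActivityEpisode(alias, prof.activity_label, start, dur))
            pending.pop(0)
            cursor = start + dur

    episodes.sort(key=lambda e: e.start_unixtime)
    for a, b in zip(episodes, episodes[1:]):
        assert a.end_unixtime <= b.start_unixtime, "schedule episodes overlap"
    return episodes


def _duty_sample_times(
    duration_s: float, rate_hz: float, duty_fraction: float, period_s: float
) -> np.ndarray:
    """Episode-relative sample times of one duty-cycled sensor."""
    on_len = duty_fraction * period_s
    n_on = max(int(round(on_len * rate_hz)), 1)
    n_periods = int(np.ceil(duration_s / period_s))
    starts = np.arange(n_periods) * period_s
    offsets = np.arange(n_on) / rate_hz
    t = (starts[:, None] + offsets[None, :]).ravel()
    return t[t < duration_s]


def _ar1_path(
    n: int, mean: float, sd: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) path with marginal distribution N(mean, sd^2)."""
    if n == 0:
        return np.empty(0)
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + innov_sd * eps[i - 1]
    return x


def _oscillation(
    t: np.ndarray,
    components: Sequence[tuple[float, float]],
    noise_sd: float,
    rng: np.random.Generator,
    axis_scale: float = 1.0,
    envelope: np.ndarray | None = None,
) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, freq in components:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += axis_scale * amp * np.sin(2.0 * np.pi * freq * t + phase)
    if envelope is not None:
        out *= envelope
    if noise_sd > 0:
        out += axis_scale * noise_sd * rng.standard_normal(t.shape)
    return out


def synthesize_streams(
    episode: ActivityEpisode,
    profile: ActivityProfile,
    config: SensorConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Emit the raw multi-rate sensor records of one episode.

    Samples exist only during each sensor's duty-on phase. Cumulative
    counters (steps, calories, distance) restart at zero per episode and are
    non-decreasing; heart rate follows an autocorrelated path around the
    profile mean; inertial channels are the profile's oscillation-plus-noise
    mixture (gravity on the accelerometer z axis). Rows sampled at the same
    instant by several sensors are merged; the result is sorted by time.
    """
    config = config or SensorConfig()
    if episode.duration_s < config.duty_period_s:
        raise ValueError(
            f"episode of {episode.duration_s:.0f} s is shorter than one duty "
            f"period ({config.duty_period_s:.0f} s)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ms = profile.motion_spectrum
    D, P = episode.duration_s, config.duty_period_s

    def _lognormal_unit_mean() -> float:
        s = BEHAVIOUR_JITTER_LOG_SD
        return float(rng.lognormal(-0.5 * s * s, s))

    jit = {
        "cal": float(np.clip(rng.normal(1.0, RATE_JITTER_SD), 0.1, None)),
        "steps": _lognormal_unit_mean(),
        "dist": _lognormal_unit_mean(),
    }
    motion_scale = float(np.clip(rng.normal(1.0, MOTION_JITTER_SD), 0.2, None))
    hr_offset = float(rng.normal(0.0, HR_EPISODE_SD)) if profile.hr_sd_bpm > 0 else 0.0

    # Slow unit-mean intensity modulations, one AR(1) step per duty period:
    # activity happens in bouts, so consecutive windows of one episode
    # differ in intensity.
    n_periods = int(np.ceil(D / P))

    def _drift(log_sd: float) -> np.ndarray:
        w = _ar1_path(n_periods, 0.0, log_sd, DRIFT_PHI, rng)
        return np.exp(w - 0.5 * log_sd * log_sd)

    move_drift = _drift(BEHAVIOUR_DRIFT_LOG_SD)
    cal_drift = _drift(CALORIE_DRIFT_LOG_SD)
    motion_drift = _drift(MOTION_DRIFT_LOG_SD)
    temp_path = _ar1_path(n_periods, 0.0, TEMP_EPISODE_SD, DRIFT_PHI, rng)

    def _per_sample(drift: np.ndarray, t: np.ndarray) -> np.ndarray:
        return drift[np.minimum((t // P).astype(int), n_periods - 1)]

    frames: list[pd.DataFrame] = []

    def add(t_rel: np.ndarray, data: Mapping[str, np.ndarray]) -> None:
        if t_rel.size:
            frames.append(
                pd.DataFrame({"unixtime": episode.start_unixtime + t_rel, **data})
            )

    # Inertial sensors (fastest, lowest duty fraction).
    t_gyro = _duty_sample_times(D, config.gyro_rate_hz, config.duty_fraction_other, P)
    axis_scales = {"X": 1.0, "Y": 0.7, "Z": 0.5}
    gyro_env = _per_sample(motion_drift, t_gyro)
    gyro_data = {}
    for axis, scale in axis_scales.items():
        gyro_data[f"gyro{axis}Accel"] = _oscillation(
            t_gyro, ms.accel, ms.noise_accel, rng,
            axis_scale=0.8 * scale * motion_scale, envelope=gyro_env,
        )
        gyro_data[f"gyro{axis}AnguVel"] = _oscillation(
            t_gyro, ms.gyro, ms.noise_gyro, rng,
            axis_scale=scale * motion_scale, envelope=gyro_env,
        )
    add(t_gyro, gyro_data)

    t_acc = _duty_sample_times(D, config.accel_rate_hz, config.duty_fraction_other, P)
    acc_env = _per_sample(motion_drift, t_acc)
    acc_data = {
        f"accel{axis}": _oscillation(
            t_acc, ms.accel, ms.noise_accel, rng,
            axis_scale=scale * motion_scale, envelope=acc_env,
        )
        for axis, scale in axis_scales.items()
    }
    # Wrist orientation: gravity projects onto a random per-episode axis mix
    # that drifts slowly as the wearer shifts posture.
    u0 = rng.standard_normal(3)
    u0 /= np.linalg.norm(u0)
    u1 = u0 + 0.35 * rng.standard_normal(3)
    u1 /= np.linalg.norm(u1)
    if t_acc.size:
        frac = (t_acc / D)[:, None]
        orient = (1.0 - frac) * u0[None, :] + frac * u1[None, :]
        orient /= np.linalg.norm(orient, axis=1, keepdims=True)
        for i, axis in enumerate(("X", "Y", "Z")):
            acc_data[f"accel{axis}"] = acc_data[f"accel{axis}"] + GRAVITY_M_PER_S2 * orient[:, i]
    add(t_acc, acc_data)

    # Heart rate: higher duty fraction than the other sensors.
    t_hr = _duty_sample_times(D, config.hr_rate_hz, config.duty_fraction_hr, P)
    add(
        t_hr,
        {
            "hrRate": hr_offset
            + _ar1_path(t_hr.size, profile.hr_mean_bpm, profile.hr_sd_bpm, HR_AR1_PHI, rng)
        },
    )

    t_temp = _duty_sample_times(D, config.temp_rate_hz, config.duty_fraction_other, P)
    if ms.noise_accel > 0:
        temp = (
            profile.skin_temp_c
            + _per_sample(temp_path, t_temp)
            + TEMP_NOISE_SD * rng.standard_normal(t_temp.size)
        )
    else:
        temp = np.full(t_temp.size, profile.skin_temp_c)
    add(t_temp, {"tempSkin": temp})

    # Cumulative counters advance as noisy non-negative increments between
    # successive samples (Poisson arrivals for steps), so within-episode
    # window deltas fluctuate around the drifting rate while the counters
    # stay monotone.
    def _noisy_counter(
        t: np.ndarray, rate: float, drift: np.ndarray, rel_sd: float = 0.4
    ) -> np.ndarray:
        gaps = np.diff(t, prepend=0.0)
        inc = rate * gaps * _per_sample(drift, t)
        inc *= np.clip(1.0 + rel_sd * rng.standard_normal(t.size), 0.0, None)
        return np.cumsum(inc)

    # Non-locomotive activities accumulate steps and distance in sparse
    # incidental bursts (fetching a coffee, a bathroom trip): a compound
    # Poisson process whose episode total still matches the calibrated rate,
    # but whose per-window deltas are mostly zero.
    def _burst_counter(t: np.ndarray, rate: float, burst_mean: float) -> np.ndarray:
        gaps = np.diff(t, prepend=0.0)
        if rate <= 0 or burst_mean <= 0:
            return np.zeros(t.size)
        n_bursts = rng.poisson(rate * gaps / burst_mean)
        return np.cumsum(rng.poisson(burst_mean * n_bursts)).astype(float)

    locomotive = profile.speed_mean_m_per_s > 0

    t_ped = _duty_sample_times(D, config.pedometer_rate_hz, config.duty_fraction_other, P)
    step_rate = profile.step_rate_steps_per_s * jit["steps"]
    if locomotive:
        step_gaps = np.diff(t_ped, prepend=0.0)
        step_lam = step_rate * step_gaps * _per_sample(move_drift, t_ped)
        steps = np.cumsum(rng.poisson(step_lam)).astype(float)
    else:
        steps = _burst_counter(t_ped, step_rate, burst_mean=40.0)
    add(t_ped, {"pedTotalSteps": steps})

    t_cal = _duty_sample_times(D, config.calories_rate_hz, config.duty_fraction_other, P)
    add(
        t_cal,
        {"cal": _noisy_counter(t_cal, profile.calorie_rate_cal_per_s * jit["cal"], cal_drift)},
    )

    t_dist = _duty_sample_times(D, config.distance_rate_hz, config.duty_fraction_other, P)
    dist_rate = profile.distance_rate_m_per_s * jit["dist"]
    if locomotive:
        dist = _noisy_counter(t_dist, dist_rate, move_drift)
        speed = (
            profile.speed_mean_m_per_s
            * jit["dist"]
            * _per_sample(move_drift, t_dist)
            * np.clip(1.0 + 0.3 * rng.standard_normal(t_dist.size), 0.0, None)
        )
    else:
        dist = _burst_counter(t_dist, dist_rate, burst_mean=30.0)
        speed = np.zeros(t_dist.size)
    with np.errstate(divide="ignore"):
        pace = np.where(speed > 1e-9, 1.0 / np.maximum(speed, 1e-9), 0.0)
    add(t_dist, {"distTotal": dist, "distSpeed": speed, "distPace": pace})

    merged = (
        pd.concat(frames, ignore_index=True)
        .groupby("unixtime", sort=True)
        .first()
        .reset_index()
    )
    for col in SENSOR_COLUMNS:
        if col not in merged.columns:
            merged[col] = np.nan
    merged["activity"] = episode.activity_label
    merged["alias"] = episode.alias
    return merged[list(RAW_COLUMNS)]


def day_directory_name(ts: float, tz: dt.tzinfo = DEFAULT_TZ) -> str:
    """Directory name for the day containing ``ts``: e.g. ``03may2018``."""
    d = dt.datetime.fromtimestamp(ts, tz)
    return f"{d.day:02d}{d.strftime('%b').lower()}{d.year:04d}"


def write_raw_files(
    records: pd.DataFrame, root: str | Path, tz: dt.tzinfo = DEFAULT_TZ
) -> list[Path]:
    """Write raw records as one CSV per (day, alias, activity).

    Files land under ``root/ddmonthyyyy/alias/activity.csv``; reading them
    back with :func:`wristmine.ingest.read_raw` reproduces the records
    exactly. Records must already be sorted by timestamp.
    """
    root = Path(root)
    if records.empty:
        return []
    if not records["unixtime"].is_monotonic_increasing:
        raise ValueError("records must be sorted by unixtime")
    paths: list[Path] = []
    days = records["unixtime"].map(lambda ts: day_directory_name(ts, tz))
    for (day, alias, activity), group in records.groupby(
        [days, "alias", "activity"], sort=True
    ):
        path = root / day / alias / f"{activity}.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        group.to_csv(path, index=False)
        paths.append(path)
    return paths
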