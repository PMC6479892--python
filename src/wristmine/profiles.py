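"""Per-activity generative calibration and sensor hardware configuration.

An :class:`ActivityProfile` holds everything the stream simulator needs to
emit realistic wrist-sensor data for one activity: the episode-duration
distribution, a heart-rate level and spread, cumulative-counter rates
(calories, steps, distance) and a motion spectrum (a small sum of sinusoids
plus white noise) for the accelerometer and gyroscope channels.

A :class:`SensorConfig` describes the wearable itself: per-sensor sampling
rates and the battery-saving duty cycle (sensors wake for a fraction of each
activation period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: The ten daily-living activity labels recognised by the pipeline.
ACTIVITIES: tuple[str, ...] = (
    "eating",
    "running",
    "sleeping",
    "classroom-session",
    "exam",
    "job",
    "homework",
    "transportation",
    "watching TV-Series",
    "reading",
)


@dataclass(frozen=True)
class MotionSpectrum:
    """Oscillation-plus-noise model for the inertial channels.

    ``accel`` and ``gyro`` are lists of ``(amplitude, frequency_hz)`` sinusoid
    components (at most two are meaningful for this simulator); ``noise_*``
    are white-noise standard deviations in the channel's own units.
    """

    accel: tuple[tuple[float, float], ...] = ()
    gyro: tuple[tuple[float, float], ...] = ()
    noise_accel: float = 0.0
    noise_gyro: float = 0.0

    def __post_init__(self) -> None:
        for amp, freq in (*self.accel, *self.gyro):
            if amp < 0 or freq < 0:
                raise ValueError("motion amplitudes and frequencies must be >= 0")
        if self.noise_accel < 0 or self.noise_gyro < 0:
            raise ValueError("noise levels must be >= 0")


@dataclass(frozen=True)
class ActivityProfile:
    """Generative parameters for one activity.

    Durations are drawn from a normal distribution clipped to
    ``[duration_min_s, duration_max_s]``. Cumulative counters advance at the
    per-second rates below; ``calorie_rate_cal_per_s`` and the distance rate
    are derived from mean episode totals over mean duration.
    """

    activity_label: str
    duration_mean_s: float
    duration_sd_s: float
    duration_min_s: float
    duration_max_s: float
    hr_mean_bpm: float
    hr_sd_bpm: float
    calories_mean: float
    distance_mean_m: float
    speed_mean_m_per_s: float
    step_rate_steps_per_s: float
    skin_temp_c: float = 33.5
    motion_spectrum: MotionSpectrum = field(default_factory=MotionSpectrum)

    def __post_init__(self) -> None:
        if self.activity_label not in ACTIVITIES:
            raise ValueError(f"unknown activity label: {self.activity_label!r}")
        if not (self.duration_min_s <= self.duration_mean_s <= self.duration_max_s):
            raise ValueError(
                f"{self.activity_label}: need duration min <= mean <= max, got "
                f"{self.duration_min_s} <= {self.duration_mean_s} <= {self.duration_max_s}"
            )
        if self.duration_sd_s < 0 or self.duration_min_s <= 0:
            raise ValueError(f"{self.activity_label}: invalid duration parameters")
        if not 40.0 <= self.hr_mean_bpm <= 220.0:
            raise ValueError(f"{self.activity_label}: hr_mean_bpm outside [40, 220]")
        for name in (
            "hr_sd_bpm",
            "calories_mean",
            "distance_mean_m",
            "speed_mean_m_per_s",
            "step_rate_steps_per_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.activity_label}: {name} must be >= 0")

    @property
    def calorie_rate_cal_per_s(self) -> float:
        """Mean calorie-burn rate, cal/s (mean episode total over mean duration)."""
        return self.calories_mean / self.duration_mean_s

    @property
    def distance_rate_m_per_s(self) -> float:
        """Mean cumulative-distance rate, m/s."""
        return self.distance_mean_m / self.duration_mean_s


@dataclass(frozen=True)
class SensorConfig:
    """Sampling rates (Hz) and duty cycling of the wrist device.

    The gyroscope is the fastest sensor; every sensor wakes once per
    ``duty_period_s`` seconds, the heart-rate sensor for ``duty_fraction_hr``
    of the period and all others for ``duty_fraction_other``.
    """

    gyro_rate_hz: float = 8.0
    accel_rate_hz: float = 8.0
    hr_rate_hz: float = 1.0
    temp_rate_hz: float = 1.0
    pedometer_rate_hz: float = 1.0
    calories_rate_hz: float = 1.0
    distance_rate_hz: float = 1.0
    duty_period_s: float = 40.0
    duty_fraction_hr: float = 0.125
    duty_fraction_other: float = 0.05

    def __post_init__(self) -> None:
        others = (
            self.accel_rate_hz,
            self.hr_rate_hz,
            self.temp_rate_hz,
            self.pedometer_rate_hz,
            self.calories_rate_hz,
            self.distance_rate_hz,
        )
        if any(r <= 0 for r in (self.gyro_rate_hz, *others)):
            raise ValueError("sampling rates must be > 0")
        if any(r > self.gyro_rate_hz for r in others):
            raise ValueError("the gyroscope must be the fastest sensor")
        if self.duty_period_s <= 0:
            raise ValueError("duty_period_s must be > 0")
        for f in (self.duty_fraction_hr, self.duty_fraction_other):
            if not 0.0 < f <= 1.0:
                raise ValueError("duty fractions must lie in (0, 1]")


def _profile_from_mapping(label: str, spec: Mapping) -> ActivityProfile:
    dur = spec["duration"]
    hr = spec["heart_rate"]
    motion = spec.get("motion", {})
    return ActivityProfile(
        activity_label=label,
        duration_mean_s=float(dur["mean"]),
        duration_sd_s=float(dur["sd"]),
        duration_min_s=float(dur["min"]),
        duration_max_s=float(dur["max"]),
        hr_mean_bpm=float(hr["mean"]),
        hr_sd_bpm=float(hr["sd"]),
        calories_mean=float(spec["calories_mean"]),
        distance_mean_m=float(spec["distance_mean_m"]),
        speed_mean_m_per_s=float(spec["speed_mean_mps"]),
        step_rate_steps_per_s=float(spec["step_rate_steps_per_s"]),
        skin_temp_c=float(spec.get("skin_temp_c", 33.5)),
        motion_spectrum=MotionSpectrum(
            accel=tuple((float(a), float(f)) for a, f in motion.get("accel", [])),
            gyro=tuple((float(a), float(f)) for a, f in motion.get("gyro", [])),
            noise_accel=float(motion.get("noise_accel", 0.0)),
            noise_gyro=float(motion.get("noise_gyro", 0.0)),
        ),
    )


def load_profiles(path: str | Path | None = None) -> dict[str, ActivityProfile]:
    """Load activity profiles from a YAML calibration file.

    With no argument, loads the calibration shipped with the package (the
    study cohort's published per-activity statistics plus the simulator's
    chosen motion spectra). Returns a mapping from activity label to profile.
    """
    if path is None:
        text = (
            resources.files("wristmine.data")
            .joinpath("default_profiles.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or not raw:
        raise ValueError("profile file must map activity labels to parameter blocks")
    return {label: _profile_from_mapping(label, spec) for label, spec in raw.items()}


def profiles_for(
    labels: Iterable[str], profiles: Mapping[str, ActivityProfile] | None = None
) -> list[ActivityProfile]:
    """Convenience: select profiles for ``labels`` (default calibration if None)."""
    table = load_profiles() if profiles is None else profiles
    return [table[label] for label in labels]
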