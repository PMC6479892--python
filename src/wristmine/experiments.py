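"""Pre-packaged validation experiments.

Each function here runs one of the package's headline checks end to end on
synthetic data — the qualitative feature-set ordering under cross-validation,
the permutation null, generator-parameter recovery, planted-meal recovery and
noise rejection in feature selection — and returns plain numbers. They are
used both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import build_cases, run_cv
from .pipeline import extract_features, simulate_cohort
from .profiles import ActivityProfile, SensorConfig, load_profiles
from .selection import best_first_select
from .synthetic import (
    DEFAULT_TZ,
    ActivityEpisode,
    expected_duration,
    generate_day_schedule,
    sample_duration,
    synthesize_streams,
)


def replicate_feature_table(seed: int, aliases: Sequence[str] = ("ana", "beto"),
                            n_days: int = 2) -> pd.DataFrame:
    """One replicate of the study: a small cohort run through the pipeline."""
    records, _ = simulate_cohort(aliases=aliases, n_days=n_days, seed=seed)
    return extract_features(records)


def ordering_replicate(seed: int, folds: int = 10) -> dict[str, float]:
    """Tree-ensemble accuracy on the time vs time+wavelet cases, plus the
    permutation null of the rule learner, for one synthetic replicate.

    The rule learner is used for the null because precision-stopped rule
    induction degrades to the majority-class default under permuted labels;
    an unpruned forest instead memorizes near-duplicate window instances.
    """
    table = replicate_feature_table(seed)
    cases = build_cases(table)
    rf_time = run_cv(cases["time"], "random_forest", table, folds=folds, seed=seed)
    rf_both = run_cv(cases["time+wavelet"], "random_forest", table, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    permuted = table.copy()
    permuted["activity"] = rng.permutation(permuted["activity"].to_numpy())
    null = run_cv(cases["time"], "ripper_rules", permuted, folds=folds, seed=seed)
    majority = 100.0 * permuted["activity"].value_counts().iloc[0] / len(permuted)
    return {
        "n_instances": float(len(table)),
        "acc_time": rf_time.accuracy,
        "acc_time_wavelet": rf_both.accuracy,
        "acc_permuted": null.accuracy,
        "majority_rate": majority,
    }


def ordering_experiment(seed: int, n_replicates: int = 10) -> pd.DataFrame:
    """Run :func:`ordering_replicate` over spawned seeds."""
    rows = []
    for i in range(n_replicates):
        rep_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        rows.append(ordering_replicate(rep_seed))
    return pd.DataFrame(rows)


def recovery_experiment(
    seed: int,
    n_episodes: int = 200,
    profiles: Mapping[str, ActivityProfile] | None = None,
    config: SensorConfig | None = None,
) -> pd.DataFrame:
    """Recover generator settings from synthesized episodes, per activity.

    Draws ``n_episodes`` durations per activity and synthesizes streams for
    them, then compares the empirical mean duration, heart rate and calorie
    rate against the generator's settings (the analytic clipped-normal mean
    for durations). Returns per-activity relative errors in percent.
    """
    profiles = profiles or load_profiles()
    config = config or SensorConfig()
    rows = []
    for idx, (label, prof) in enumerate(sorted(profiles.items())):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
        )
        durations, hr_means, cal_rates = [], [], []
        for _ in range(n_episodes):
            d = sample_duration(prof, rng)
            durations.append(d)
            ep = ActivityEpisode("sim", label, 1.0e9, max(d, config.duty_period_s))
            rec = synthesize_streams(ep, prof, config, rng)
            hr = rec["hrRate"].dropna()
            hr_means.append(hr.mean())
            cal = rec[["unixtime", "cal"]].dropna()
            elapsed = cal["unixtime"].iloc[-1] - ep.start_unixtime
            if elapsed > 0:
                cal_rates.append(cal["cal"].iloc[-1] / elapsed)
        exp_dur = expected_duration(prof)
        rows.append(
            {
                "activity": label,
                "duration_err_pct": 100.0 * abs(np.mean(durations) - exp_dur) / exp_dur,
                "hr_err_pct": 100.0
                * abs(np.mean(hr_means) - prof.hr_mean_bpm)
                / prof.hr_mean_bpm,
                "cal_rate_err_pct": 100.0
                * abs(np.mean(cal_rates) - prof.calorie_rate_cal_per_s)
                / prof.calorie_rate_cal_per_s,
            }
        )
    return pd.DataFrame(rows).set_index("activity")


def duration_se_oracle(
    profile: ActivityProfile, n_episodes: int, n_mc: int = 200_000, seed: int = 987654321
) -> float:
    """Brute-force standard error of the mean of ``n_episodes`` sampled
    durations, from an independent large Monte-Carlo run of the sampler."""
    rng = np.random.default_rng(seed)
    draws = np.clip(
        rng.normal(profile.duration_mean_s, profile.duration_sd_s, n_mc),
        profile.duration_min_s,
        profile.duration_max_s,
    )
    return float(draws.std(ddof=1) / np.sqrt(n_episodes))


def meal_recovery_experiment(
    seed: int, n_schedules: int = 100, profiles: Mapping[str, ActivityProfile] | None = None
) -> float:
    """Fraction of random day schedules whose planted meals are counted
    back exactly by the meal classifier (1.0 = perfect recovery)."""
    from .habits import count_meals

    profiles = profiles or load_profiles()
    day_profiles = [profiles[a] for a in ("sleeping", "eating", "transportation", "homework")]
    rng = np.random.default_rng(seed)
    all_meals = ("breakfast", "lunch", "dinner")
    exact = 0
    for i in range(n_schedules):
        planted = tuple(m for m in all_meals if rng.random() < 0.8)
        date = dt.date(2018, 5, 3) + dt.timedelta(days=int(rng.integers(0, 60)))
        schedule = generate_day_schedule(
            day_profiles, date, "sim", int(rng.integers(2**31)), meals=planted
        )
        eating_starts = [
            ep.start_unixtime for ep in schedule if ep.activity_label == "eating"
        ]
        counts = count_meals(eating_starts, DEFAULT_TZ)
        want = (
            int("breakfast" in planted),
            int("lunch" in planted),
            int("dinner" in planted),
            0,
        )
        if tuple(counts) == want:
            exact += 1
    return exact / n_schedules


def selection_noise_experiment(
    seed: int,
    n_replicates: int = 100,
    n_instances: int = 500,
    n_informative: int = 3,
    n_noise: int = 10,
) -> float:
    """Fraction of replicates in which CFS selects no pure-noise feature.

    Each replicate draws ``n_informative`` class-shifted features and
    ``n_noise`` label-independent ones; a replicate counts as clean when the
    selected subset contains informative features only.
    """
    clean = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        y = rng.integers(0, 3, n_instances)
        data = {f"noise{j}": rng.normal(size=n_instances) for j in range(n_noise)}
        for j in range(n_informative):
            data[f"info{j}"] = y + rng.normal(scale=0.5, size=n_instances)
        table = pd.DataFrame(data)
        result = best_first_select(table, y)
        if result.selected_feature_names and not any(
            name.startswith("noise") for name in result.selected_feature_names
        ):
            clean += 1
    return clean / n_replicates
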