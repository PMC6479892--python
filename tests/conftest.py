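import numpy as np
import pandas as pd
import pytest

import wristmine as wm


@pytest.fixture(scope="session")
def profiles():
    return wm.load_profiles()


@pytest.fixture(scope="session")
def sensor_config():
    return wm.SensorConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """One alias over two days: raw records plus ground-truth episodes."""
    records, episodes = wm.simulate_cohort(aliases=("ana",), n_days=2, seed=3)
    return records, episodes


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Full 55-feature instance table for the small cohort."""
    records, _ = small_cohort
    return wm.extract_features(records)


def make_latched_records(
    n_seconds: int,
    alias: str = "ana",
    activity: str = "homework",
    t0: float = 1_525_300_000.0,
    **channel_values,
):
    """Hand-built 1 Hz fully-observed record table for consolidation tests.

    Every sensor channel defaults to a constant; pass arrays or scalars to
    override individual channels (e.g. ``pedTotalSteps=np.arange(n)``).
    """
    t = t0 + np.arange(n_seconds, dtype=float)
    data = {"unixtime": t}
    defaults = {c: 1.0 for c in wm.RAW_COLUMNS[1:-2]}
    defaults.update({"pedTotalSteps": 0.0, "cal": 0.0, "distTotal": 0.0})
    for col, default in defaults.items():
        value = channel_values.get(col, default)
        data[col] = np.broadcast_to(np.asarray(value, dtype=float), t.shape).copy()
    frame = pd.DataFrame(data)
    frame["activity"] = activity
    frame["alias"] = alias
    return frame[list(wm.RAW_COLUMNS)]
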