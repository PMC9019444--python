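import numpy as np
import pandas as pd
import pytest

from eegstress import FEATURE_COLUMNS, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Two subjects per group, baseline + one intervention, 60-s segments."""
    return SimulationConfig(
        n_per_group=2, conditions=("baseline", "MI-1"), segment_duration=60.0,
        seed=42,
    )


def synthetic_feature_table(
    n_per_group=9,
    conditions=("baseline", "MI-1"),
    channels=("C3", "C4"),
    bands=("delta", "alpha"),
    n_windows=4,
    effect=None,
    seed=0,
):
    """Feature table drawn directly from Gaussians, bypassing the EEG path.

    ``effect`` maps (group, condition, band) -> additive shift applied to
    every feature column, letting classifier tests inject a known signal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, prefix in (("male", "m"), ("female", "f")):
        for i in range(1, n_per_group + 1):
            sid = f"{prefix}{i:02d}"
            for cond in conditions:
                for ch in channels:
                    for band in bands:
                        shift = (effect or {}).get((group, cond, band), 0.0)
                        for w in range(n_windows):
                            vals = rng.standard_normal(len(FEATURE_COLUMNS))
                            rows.append({
                                "subject_id": sid, "group": group,
                                "condition": cond, "channel": ch,
                                "band": band, "window": w,
                                **{c: v + shift for c, v in
                                   zip(FEATURE_COLUMNS, vals)},
                                "degenerate": False,
                            })
    return pd.DataFrame(rows)


@pytest.fixture
def feature_table():
    return synthetic_feature_table()
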