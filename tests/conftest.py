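import numpy as np
import pandas as pd
import pytest

from cravemap import synth
from cravemap.config import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return PipelineConfig(n_subjects=2, grid_shape=(8, 8, 8), seed=7)


@pytest.fixture
def default_config():
    return PipelineConfig(seed=7)


@pytest.fixture
def one_design(small_config):
    return synth.generate_design(small_config, seed=3)[0]


@pytest.fixture
def run_events(one_design):
    ev = one_design.events_frame()
    return ev[ev["run"] == 1].reset_index(drop=True)


@pytest.fixture
def motion6(small_config, rng):
    return synth.simulate_motion(small_config.n_volumes, rng)


def toy_events(n_trials=6, spacing=30.0, duration=8.0, conditions=None, run=1):
    """Small synthetic event table with generous spacing."""
    if conditions is None:
        conditions = ["positive", "negative", "now"] * (n_trials // 3 + 1)
    rows = []
    for i in range(n_trials):
        rows.append({"onset": 5.0 + i * spacing, "duration": duration,
                     "condition": conditions[i], "cue_id": 1 + i % 2,
                     "stimulus_id": i, "run": run})
    return pd.DataFrame(rows)
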