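import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from flowparse.observers import (
    GenerativeConfig,
    sample_observer,
    simulate_experiment_session,
    simulate_power_dataset,
    simulate_ratings,
)


@pytest.fixture(scope="session")
def generative_config() -> GenerativeConfig:
    return GenerativeConfig()


@pytest.fixture(scope="session")
def power_trials(generative_config) -> pd.DataFrame:
    """Small power-mode dataset (6 participants) shared across tests."""
    rng = np.random.default_rng(1234)
    return simulate_power_dataset(generative_config, 6, rng)


@pytest.fixture(scope="session")
def session_trials(generative_config) -> pd.DataFrame:
    """Staircase-driven sessions for 3 participants, all conditions."""
    rng = np.random.default_rng(99)
    frames = []
    for i in range(3):
        obs = sample_observer(generative_config, f"s{i + 1:02d}", rng)
        frames.append(simulate_experiment_session(generative_config, obs, rng))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def session_ratings() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.concat(
        [simulate_ratings(f"s{i + 1:02d}", rng) for i in range(3)],
        ignore_index=True,
    )
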