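import numpy as np
import pytest

from aratscore import (
    PipelineConfig,
    SimulationConfig,
    build_feature_table,
    generate_dataset,
)
from aratscore.pipeline import preprocess_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but complete cohort: 6 subjects, 1 session each."""
    return SimulationConfig(n_subjects=6, sessions_per_subject=1, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_segments(small_dataset, small_config):
    pipeline_cfg = PipelineConfig(simulation=small_config)
    return preprocess_dataset(small_dataset, pipeline_cfg)


@pytest.fixture(scope="session")
def small_table(small_segments):
    return build_feature_table(small_segments)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
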