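from datetime import datetime

import pytest

from tidegam.detections import (
    assemble_sequences,
    build_model_table,
    filter_service_days,
)
from tidegam.synthetic_data import SyntheticConfig, simulate_study
from tidegam.tide_clock import synth_tide_schedule


@pytest.fixture(scope="session")
def tiny_tides():
    """Three days of a regular 12.5 h semidiurnal schedule."""
    return synth_tide_schedule(datetime(2023, 3, 1), 3)


@pytest.fixture(scope="session")
def small_config():
    """A small synthetic campaign for fast unit-level pipeline tests."""
    return SyntheticConfig(seed=42, n_cameras=8, n_days=25,
                           start=datetime(2023, 4, 20),
                           sequences_per_camera_day=1.5)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_table(small_study):
    triggers, deployments, tides, _truth = small_study
    sequences = filter_service_days(assemble_sequences(triggers), deployments)
    return build_model_table(sequences, deployments, tides)
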