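from __future__ import annotations

import numpy as np
import pytest

from evrad import SimulationConfig, simulate_cohort, simulate_lesion_image


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """A default-condition cohort shared across read-only tests."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def phantom(default_config):
    """One responder-class lesion phantom shared across read-only tests."""
    return simulate_lesion_image(default_config, True, "P0001")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
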