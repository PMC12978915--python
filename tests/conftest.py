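import numpy as np
import pytest

from emgmap import (
    ALL_CHANNELS,
    default_activation_map,
    preprocess_session,
    scaled_down_config,
    simulate_session,
)

#: Two muscle pairs (4 channels) for fast session-level tests.
FOUR_CHANNELS = tuple(
    c for c in ALL_CHANNELS if c.muscle.value in ("deltoid", "serratus_anterior")
)

#: Schema for reading back scaled-down synthetic sessions without duration warnings.
SCALED_SCHEMA = {"check_durations": False}


@pytest.fixture(scope="session")
def tiny_config():
    return scaled_down_config(n_participants=3, seed=7)


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    return simulate_session("p01", tiny_config, default_activation_map(), 123)


@pytest.fixture(scope="session")
def normalized_session(tiny_session):
    session, scales = preprocess_session(tiny_session.copy())
    return session, scales
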