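"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from mseqrc.starfield import FlowCondition
from mseqrc.synthetic import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def roll33_dataset():
    """12 LN neurons, 8 Roll 33 trials each, one shared m-sequence trial."""
    config = SimConfig(
        n_neurons=12,
        conditions=[FlowCondition(0.33, 0.0, 0.0, "roll33")],
    )
    return simulate_experiment(config, 42)


@pytest.fixture(scope="session")
def impulse_size_dataset():
    """12 neurons driven at the three impulse sizes with proportional gains."""
    config = SimConfig(
        n_neurons=12,
        conditions=[
            FlowCondition(0.18, 0.0, 0.0, "roll18"),
            FlowCondition(0.33, 0.0, 0.0, "roll33"),
            FlowCondition(0.48, 0.0, 0.0, "roll48"),
        ],
    )
    return simulate_experiment(config, 7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 neurons x 2 conditions x 4 trials, for structural/pipeline tests."""
    config = SimConfig(
        n_neurons=3,
        n_trials=4,
        conditions=[
            FlowCondition(0.33, 0.0, 0.0, "roll33"),
            FlowCondition(0.33, 50.0, 0.0, "er50"),
        ],
    )
    return simulate_experiment(config, 9)
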