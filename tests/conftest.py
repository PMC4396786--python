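import numpy as np
import pytest

from allosilence.simulate import simulate_experiment, small_config


@pytest.fixture(scope="session")
def tiny_exp():
    """One small but fully featured synthetic experiment, shared read-only."""
    return simulate_experiment(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
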