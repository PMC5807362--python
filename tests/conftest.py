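import numpy as np
import pytest

from bdchemo.synthetic import ScenarioSpec, generate_experiment


@pytest.fixture(scope="session")
def both_experiment():
    """One standard 9-dose x 3-replicate cytotoxic experiment + truth."""
    spec = ScenarioSpec(scenario="both", seed=42)
    return generate_experiment(spec)


@pytest.fixture(scope="session")
def rich_experiment():
    """A replicate-rich experiment (better rate identifiability)."""
    spec = ScenarioSpec(scenario="both", seed=7, replicates=30)
    return generate_experiment(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
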