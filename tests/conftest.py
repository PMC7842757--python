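import numpy as np
import pytest

from tonebias.observers import ObserverSpec, simulate_static_observer
from tonebias.perceptron import PerceptronParams
from tonebias.protocols import generate_block


def make_static_log(protocol="control", a=1.0, b=0.0, sigma=0.1,
                    n_trials=220, block_seed=0, obs_seed=1):
    """Generate a block and run a fixed-parameter observer through it."""
    block = generate_block(protocol, n_trials, block_seed)
    spec = ObserverSpec("static", PerceptronParams(a, b, sigma), seed=obs_seed)
    return simulate_static_observer(spec, block)


@pytest.fixture(scope="session")
def control_block():
    """A 220-trial control block with a fixed seed."""
    return generate_block("control", 220, 11)


@pytest.fixture(scope="session")
def big_control_block():
    """A large control block for distributional checks."""
    return generate_block("control", 10_000, 12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
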