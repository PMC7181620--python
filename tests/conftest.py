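import numpy as np
import pytest

import triconf as tc


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def exp1_config():
    return tc.standard_configurations(1)[0]


@pytest.fixture(scope="session")
def difference_params():
    return tc.ObserverParams(
        sigma=0.5,
        alpha=30.0,
        criteria=(0.2, 0.4, 0.7),
        lapse=0.02,
        rule="difference",
    )


@pytest.fixture(scope="session")
def small_session(difference_params):
    """A 336-trial Experiment-1 synthetic session (the standard design)."""
    return tc.generate_session(1, difference_params, seed=42)


def random_simplex(rng, n):
    """Uniform points on the 3-simplex (for property checks)."""
    g = rng.standard_gamma(1.0, size=(n, 3))
    return g / g.sum(axis=1, keepdims=True)
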