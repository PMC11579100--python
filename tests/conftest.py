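import numpy as np
import pytest

from optidose.fixtures import DEFAULT_SEED


@pytest.fixture
def rng():
    return np.random.default_rng(DEFAULT_SEED)


@pytest.fixture(scope="session")
def fast_sim():
    """Slightly relaxed solver tolerances for the heavy end-to-end runs."""
    return {"rtol": 1e-8, "atol": 1e-10}
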