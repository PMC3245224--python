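import numpy as np
import pytest

from episodenet.dynamics import OdeSpec, simulate_rossler


@pytest.fixture(scope="session")
def rossler_series():
    """A chaotic Rössler x-series long enough for a few hundred cycles."""
    return simulate_rossler(OdeSpec("rossler", dt=0.05, n_steps=30_000,
                                    transient_steps=3_000))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
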