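import numpy as np
import pytest

from calofs import SynthSpec, synthetic_split


@pytest.fixture(scope="session")
def small_split():
    """Well-separated 2-class dataset: 3 informative + 5 noise features."""
    data, informative = synthetic_split(
        SynthSpec(n_samples=120, n_informative=3, n_noise=5, delta=3.0, seed=7)
    )
    return data, informative


@pytest.fixture
def rng():
    return np.random.default_rng(11)
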