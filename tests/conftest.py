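import numpy as np
import pytest

from rhodotools import synthgen


@pytest.fixture(scope="session")
def default_photocycle():
    """Noiseless flash-photolysis matrix at the default proton-pump scheme."""
    series, truth = synthgen.make_photocycle_series(seed=0)
    return series, truth


@pytest.fixture(scope="session")
def reference_sequence():
    from rhodotools.opsinseq import load_reference

    return load_reference()[1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
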