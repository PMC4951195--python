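import numpy as np
import pytest

from becgrowth import ModelParameters


@pytest.fixture
def fitted_params() -> ModelParameters:
    """The parameter set fitted to the injury time course (package defaults)."""
    return ModelParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
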