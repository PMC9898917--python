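import numpy as np
import pytest

from thaggfip import synthgen


@pytest.fixture
def stability_truth():
    return synthgen.default_stability_truth()


@pytest.fixture
def rng():
    return np.random.default_rng(20230203)
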