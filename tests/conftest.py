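import numpy as np
import pytest

from micejm import SimConfig, apply_mcar_mask, simulate_complete


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def masked_glom():
    """One study-design dataset: n=100, beta=3, Y and W1 missing on rows 0-49."""
    data = simulate_complete(SimConfig(n=100, beta=3.0, seed=7))
    return apply_mcar_mask(data, 50)
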