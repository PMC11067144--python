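import numpy as np
import pytest

from lcnbm import PhantomDesign


@pytest.fixture
def small_design():
    """Four tiny groups, complete data: fast image-based end-to-end runs."""
    return PhantomDesign(n_per_group=(4, 4, 4, 4), missing_lc_i={}, seed=11)


@pytest.fixture
def noiseless_design():
    return PhantomDesign(noise_sigma=0.0, n_distractors=0, missing_lc_i={}, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
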