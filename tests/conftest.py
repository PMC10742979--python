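import numpy as np
import pytest

from wunet.synthetic import SyntheticConfig, generate_paired_stack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_paired():
    """A small 64-pixel paired stack shared by fast structural tests."""
    cfg = SyntheticConfig(section_size=64, n_depths=4, cell_density=6,
                          seed=11)
    return generate_paired_stack(cfg)


@pytest.fixture(scope="session")
def midsize_paired():
    """A 128-pixel paired stack for metric-recovery checks."""
    cfg = SyntheticConfig(section_size=128, n_depths=8, cell_density=12,
                          seed=7)
    return generate_paired_stack(cfg)
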