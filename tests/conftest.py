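import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """A modest LD-bearing panel shared across unit tests."""
    import gssim
    return gssim.generate_founder_panel(n_lines=120, n_loci=300,
                                        n_chromosomes=3, total_map_cM=450.0,
                                        seed=11)


@pytest.fixture(scope="session")
def default_panel():
    """The full-size default founder panel."""
    import gssim
    return gssim.generate_founder_panel(seed=99)
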