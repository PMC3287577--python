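import numpy as np
import pytest

import bayesode as bo


@pytest.fixture(scope="session")
def default_inputs():
    """IL-10 and macrophage forcing callables at the default profile specs."""
    return (
        bo.profile_function(bo.IL10_DEFAULT),
        bo.profile_function(bo.MACROPHAGE_DEFAULT),
    )


@pytest.fixture(scope="session")
def small_grid():
    """A short grid (same step as the study grid) for fast unit tests."""
    return bo.TimeGrid(t0=0.0, h=0.04, m=120)


@pytest.fixture(scope="session")
def clean_small_dataset(small_grid):
    """Noise-free TGF-beta data at V=5, K=2 on the short grid."""
    return bo.generate_dataset({"V": 5.0, "K": 2.0}, grid=small_grid)
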