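import numpy as np
import pytest

import firetree as ft


@pytest.fixture(scope="session")
def reference_config():
    """Scalar reference configuration (retentions 0.9/0.4, a=0.1, thresholds 0.2/0.8)."""
    return ft.scalar_reference_config(seed=0)


@pytest.fixture(scope="session")
def bimodal_config():
    """Fast-growth configuration with a two-peaked stationary cover distribution."""
    return ft.scalar_bimodal_config(seed=0)


@pytest.fixture(scope="session")
def three_class_config():
    return ft.three_class_reference_config(seed=0)


@pytest.fixture(scope="session")
def reference_chain(reference_config):
    return ft.discretize(reference_config, delta=0.01)


@pytest.fixture(scope="session")
def bimodal_chain(bimodal_config):
    return ft.discretize(bimodal_config, delta=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
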