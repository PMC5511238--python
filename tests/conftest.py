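import numpy as np
import pytest

from dlradiomics import (
    NetworkSpec,
    PhantomConfig,
    build_network,
    generate_cohort,
    generate_phantom,
)

#: slim architecture used throughout the tests; the real default
#: (6 conv layers, fc 4096) is exercised only where the test is about it
TINY_SPEC = NetworkSpec(
    n_conv_layers=2,
    conv_filters=(4, 8),
    fc_neurons=16,
    n_input_channels=2,
)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def one_phantom(phantom_config):
    return generate_phantom(phantom_config, label=1, seed=7)


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    """Six phantoms, three per class."""
    return generate_cohort(3, phantom_config, seed=5)


@pytest.fixture(scope="session")
def tiny_net():
    return build_network(TINY_SPEC, seed=0)
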