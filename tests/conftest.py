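import numpy as np
import pytest

from modtransfer.models import DeviceGroupSpec, MDNNSpec, SDNNSpec
from modtransfer.synthetic import make_transfer_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_sdnn_spec():
    return SDNNSpec(input_length=32, n_classes=3, conv_filters=(4, 4),
                    kernel_size=3, pool_size=2)


@pytest.fixture
def tiny_mdnn_spec():
    return MDNNSpec.single_group(n_channels=3, input_length=32, n_classes=4,
                                 conv_filters=(4, 4), kernel_size=3,
                                 head_units=(16,))


@pytest.fixture
def two_group_mdnn_spec():
    return MDNNSpec(groups=(DeviceGroupSpec("watch", 2, 40),
                            DeviceGroupSpec("glasses", 2, 24)),
                    n_classes=3, conv_filters=(4,), kernel_size=3,
                    head_units=(12,))


@pytest.fixture(scope="session")
def benchmark():
    """The published synthetic transfer benchmark (seed 11)."""
    return make_transfer_benchmark(seed=11)
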