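import numpy as np
import pytest

from boneal import phantoms as ph
from boneal.preprocessing import standardize
from boneal.unet import UNetConfig, build_unet

TINY_NET = UNetConfig(depth=2, base_filters=4, input_size=(64, 64), seed=0, batch_size=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_records():
    """Ten 64x64 phantoms with the default nuisance variation."""
    return ph.generate_records(10, seed=0)


@pytest.fixture(scope="session")
def small_training_items(small_records):
    return [(standardize(r.image).pixels.astype(np.float32), r.mask) for r in small_records]


@pytest.fixture(scope="session")
def overfit_net(small_training_items):
    """A tiny U-Net overfit for 20 epochs on the 10-phantom pool."""
    net = build_unet(TINY_NET)
    losses = [net.train_epoch(small_training_items) for _ in range(20)]
    return net, losses
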