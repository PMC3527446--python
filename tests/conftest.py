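import numpy as np
import pytest

from buho import ChannelImage, SyntheticSpec, default_bank, generate_field


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field():
    """One small rendered field with ground truth, shared across tests."""
    spec = SyntheticSpec(side=256, n_cells=6, seed=42)
    return generate_field(spec)


def make_channel(pixels, bit_depth=16, pixel_size_um=0.2, role="foci"):
    return ChannelImage(
        pixels=np.asarray(pixels, dtype=float),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        role=role,
    )


@pytest.fixture()
def channel_factory():
    return make_channel
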