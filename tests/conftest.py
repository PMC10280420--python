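import numpy as np
import pytest

import niftimark as nm


@pytest.fixture(scope="session")
def logo64():
    return nm.make_watermark(64)


@pytest.fixture(scope="session")
def key64():
    return nm.default_key(64)


@pytest.fixture(scope="session")
def phantom512():
    """512x512 phantom wrapped as a GraySlice already on the [0,255] scale."""
    px = nm.make_phantom_slice(512, 7)
    return nm.GraySlice(pixels=px, rescale_lo=0.0, rescale_hi=255.0,
                        side=512)


@pytest.fixture(scope="session")
def cfg_default(key64):
    return nm.EmbedConfig(mu=0.01, key=key64)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
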