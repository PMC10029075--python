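import numpy as np
import pytest

from exmquant import synthetic as syn


@pytest.fixture(scope="session")
def blob_image():
    """A deterministic textured 2D test image (blob field)."""
    rng = np.random.default_rng(42)
    return syn.render_blobs((96, 96), *syn._blob_params(rng, 25, (96, 96), 8.0))


@pytest.fixture(scope="session")
def expansion_pair_4x():
    """Clean 4x expansion pair with truth, shared across registration tests."""
    return syn.gen_expansion_pair(
        scale=4.0, seed=11, pre_shape=(128, 128), n_objects=40, noise_sd=2.0
    )
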