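import numpy as np
import pytest

from perivasc import EnFaceImage, Modality, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Reduced-size generator config used to keep image tests fast."""
    return SyntheticConfig(seed=11, side_px=96, n_per_group=(3, 2, 3))


def make_image(pixels, modality=Modality.STRUCTURAL, **kw):
    return EnFaceImage(np.asarray(pixels), modality, **kw)


@pytest.fixture
def make_enface():
    return make_image
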