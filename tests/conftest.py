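import numpy as np
import pytest

import stainkit as sk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def he_patch():
    """Noise-free two-stain blob patch with its ground truth."""
    spec = sk.SyntheticPatchSpec(seed=9, density_scale=(1.0, 0.6), od_noise_sd=0.0)
    return sk.generate_he_patch(spec)


@pytest.fixture
def bordered_patch(he_patch):
    """Blob patch with a white (background) top border."""
    rgb, basis, dens = he_patch
    img = rgb.copy()
    img[:4, :, :] = 255
    return img
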