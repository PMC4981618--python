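import numpy as np
import pytest

import wmlseg as w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_case():
    """One default noisy 64^3 phantom, shared across tests (read-only)."""
    return w.generate_phantom(w.PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def clean_case():
    """Noiseless default phantom with 5 WM lesions of 4-30 voxels."""
    spec = w.PhantomSpec(seed=5, flair_noise_sd=0.0, t1_noise_sd=0.0)
    return w.generate_phantom(spec)


@pytest.fixture
def small_volume(rng):
    return w.Volume(rng.normal(100.0, 5.0, (8, 8, 8)), (1.0, 1.0, 1.0))


def make_labels(arr, spacing=(1.0, 1.0, 1.0)):
    """TissueLabels from a raw uint8 array."""
    from wmlseg.tissue_model import TissueLabels

    return TissueLabels(w.Volume(np.asarray(arr, dtype=np.uint8), spacing))
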