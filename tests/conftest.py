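import warnings

import numpy as np
import pytest

from ctperf.phantom import build_phantom, default_spec
from ctperf.pipeline import train_default_models

warnings.filterwarnings("ignore", message="constant reference frame")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless standard phantom: core 12 mL, penumbra 40 mL, 5+3 vessels."""
    return build_phantom(default_spec(seed=1))


@pytest.fixture(scope="session")
def validity_models():
    """IV (AIF, VOF) and LV classifiers trained on synthetic curves."""
    return train_default_models(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
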