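import numpy as np
import pytest

from sparsect import phantoms as ph
from sparsect import tomography as tg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shepp128():
    return ph.make_shepp_logan(128)


@pytest.fixture(scope="session")
def geo128():
    return tg.Geometry.for_image(128, 180, m1=185)


@pytest.fixture(scope="session")
def small_geo():
    """Geometry for 32x32 images, 30 angles."""
    return tg.Geometry.for_image(32, 30)
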