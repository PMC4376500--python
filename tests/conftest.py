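import numpy as np
import pytest

from pcbp import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_phantom():
    """A medium-size benign phantom with a known boundary."""
    return make_phantom(PhantomSpec("benign", rows=160, cols=200, seed=42))


@pytest.fixture(scope="session")
def malignant_phantom():
    return make_phantom(
        PhantomSpec(
            "malignant",
            rows=160,
            cols=200,
            edge_sigma=4.0,
            irregularity=0.25,
            n_lobes=5,
            heterogeneity=0.2,
            seed=43,
        )
    )
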