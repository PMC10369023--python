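import numpy as np
import pytest

from distsig.vision import ObserverModel


@pytest.fixture(scope="session")
def obs() -> ObserverModel:
    """Default trichromat observer (Weber 0.05, luminance 0.05, 3 cpd)."""
    return ObserverModel.default()


@pytest.fixture(scope="session")
def dichromat() -> ObserverModel:
    return ObserverModel(weber_fractions=(0.05, 0.05), luminance_weber=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
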