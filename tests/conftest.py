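import numpy as np
import pytest

from puffsense.optics import (
    DEFAULT_BANDS,
    ParticleOpticalProperties,
    build_extinction_matrix,
)


@pytest.fixture(scope="session")
def optics():
    return ParticleOpticalProperties()


@pytest.fixture(scope="session")
def ext(optics):
    """Default extinction matrix; built once per session (Mie-heavy)."""
    return build_extinction_matrix(optics=optics)


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_BANDS


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
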