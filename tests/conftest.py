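import pathlib
import sys

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from cryophase import MaterialParams, SpectralGrid


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def grid64() -> SpectralGrid:
    return SpectralGrid(64)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
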