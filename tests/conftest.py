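import numpy as np
import pytest

from spcryo.ctf import CTFParams
from spcryo.synthetic import make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default protein-like phantom used across module tests."""
    return make_phantom(box=48, pixel_size=3.0, seed=2)


@pytest.fixture(scope="session")
def phantom_volume(phantom):
    return phantom.volume()


@pytest.fixture(scope="session")
def ctf300():
    """Typical 300 kV imaging conditions at 15000 Å underfocus."""
    return CTFParams(15000.0, 15000.0, pixel_size=3.0)


def correlate(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


@pytest.fixture(scope="session")
def cc():
    return correlate
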