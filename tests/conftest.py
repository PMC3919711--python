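import numpy as np
import pytest

from gapring import CellParams, free_cycle


@pytest.fixture(scope="session")
def cell() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def cycle(cell):
    """Free-cell limit cycle at default parameters (shared, expensive)."""
    return free_cycle(cell)


@pytest.fixture(scope="session")
def period(cycle) -> float:
    return cycle["T"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
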