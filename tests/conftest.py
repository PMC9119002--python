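import numpy as np
import pytest

from polarasm import (PROBE_PRESETS, CurvilinearProbe, PolarGrid, Pulse)


@pytest.fixture(scope="session")
def c52v() -> CurvilinearProbe:
    return PROBE_PRESETS["c52v"]


@pytest.fixture(scope="session")
def probe_5c1() -> CurvilinearProbe:
    return PROBE_PRESETS["5c1"]


@pytest.fixture(scope="session")
def pulse() -> Pulse:
    return Pulse(3.5e6, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid(c52v) -> PolarGrid:
    theta = np.linspace(-0.4, 0.4, 64)
    r = c52v.radius_r0 + 0.22e-3 * np.arange(20)
    return PolarGrid(theta, r)
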