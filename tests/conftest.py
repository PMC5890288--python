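import numpy as np
import pytest

from phenomatch.synthetic import CycleParams, make_scene


@pytest.fixture
def db_cycle() -> CycleParams:
    """A deciduous-broadleaf-like seasonal cycle."""
    return CycleParams(baseline=0.33, amplitude=0.12, rising_midpoint=130.0,
                       rising_rate=0.18, falling_midpoint=280.0,
                       falling_rate=0.12)


@pytest.fixture
def db_scene():
    return make_scene("testsite", "DB", [2010], seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100315)
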