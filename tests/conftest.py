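import numpy as np
import pytest

from graindiel import GrainSpec, bundled_path, load_grain_spec


@pytest.fixture(scope="session")
def corn_ema() -> GrainSpec:
    """High-moisture corn parameter set (explicit bulk density, M_c = 0.16)."""
    return load_grain_spec(bundled_path("corn_highmoisture_ema"))


@pytest.fixture(scope="session")
def corn_two_phase() -> GrainSpec:
    """Settled corn parameter set with modeled bulk density."""
    return load_grain_spec(bundled_path("corn_twophase"))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
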