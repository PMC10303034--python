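import numpy as np
import pytest

import nanodose as nd
from nanodose.scoring import depth_dose
from nanodose.transport import TransportConfig, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def beam105():
    return nd.beam_105()


@pytest.fixture(scope="session")
def beam220():
    return nd.beam_220()


@pytest.fixture(scope="session")
def water_material():
    return nd.water()


@pytest.fixture(scope="session")
def water_run_105(beam105, water_material):
    """A 1e6-history plain-water run under the 105 kVp beam."""
    return run_simulation(beam105, water_material,
                          config=TransportConfig(n_histories=1_000_000,
                                                 rng_seed=42))


@pytest.fixture(scope="session")
def water_curve_105(water_run_105):
    return depth_dose(water_run_105)
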