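import numpy as np
import pytest

from decidemri import DecideParams, ModelConstants, build_protocol
from decidemri.synthetic_data import PhantomSpec, make_phantom, simulate_series


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def protocol():
    return build_protocol("decide_default", dedup=True)


@pytest.fixture(scope="session")
def table1_params() -> DecideParams:
    """Unregistered-data mean parameter set used as the worked example."""
    return DecideParams(s0=1.0, f=0.225, d=0.0015, d_star=0.0385, t2fb=181.1, v=0.306)


@pytest.fixture(scope="session")
def small_phantom(constants):
    """A small smooth phantom: (params, mask)."""
    spec = PhantomSpec(shape=(12, 12, 6), seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_series(small_phantom, protocol, constants):
    params, mask = small_phantom
    return simulate_series(params, mask, protocol, constants, spacing=(2.5, 2.5, 3.0))
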