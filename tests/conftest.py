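import numpy as np
import pytest

from aperiodic import sim_ts
from aperiodic.core import AperiodicParams, PeriodicParams, SimSpec, TimeSeries


@pytest.fixture(scope="session")
def white_noise() -> TimeSeries:
    return sim_ts.sim_powerlaw(7500, 250.0, 0.0, seed=101)


@pytest.fixture(scope="session")
def pink_noise() -> TimeSeries:
    return sim_ts.sim_powerlaw(7500, 250.0, 1.0, seed=102)


@pytest.fixture(scope="session")
def brown_noise() -> TimeSeries:
    return sim_ts.sim_powerlaw(7500, 250.0, 2.0, seed=103)


@pytest.fixture(scope="session")
def sine_10hz() -> TimeSeries:
    t = np.arange(7500) / 250.0
    return TimeSeries(np.sin(2 * np.pi * 10.0 * t), 250.0)


@pytest.fixture
def combined_spec() -> SimSpec:
    return SimSpec(
        aperiodic=AperiodicParams(exponent=1.5),
        periodic=PeriodicParams(freq=10.0, rel_power=1.0),
        seed=104,
    )
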