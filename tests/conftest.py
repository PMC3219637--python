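import numpy as np
import pytest

from dualsim import (
    ABMConfig,
    EnvironmentSeries,
    FitnessParams,
    SawtoothSpec,
    make_sawtooth,
    make_slow_rise_crash,
)


@pytest.fixture
def cycle4_env():
    """The [0,1,2,3] repeating environment (single cycle tile)."""
    return make_sawtooth(SawtoothSpec(rise_length=3, rise_step=1.0,
                                      crash_length=1, n_cycles=1))


@pytest.fixture
def cycle4_env_long():
    """Fifty cycles of [0,1,2,3] for trajectory/periodicity work."""
    return make_sawtooth(SawtoothSpec(rise_length=3, rise_step=1.0,
                                      crash_length=1, n_cycles=50))


@pytest.fixture
def fig1_env():
    """Slow 300-step rise from -1 to +1 with a single-step crash, 10 cycles:
    the default artificial ABM driver."""
    return make_slow_rise_crash(rise_length=300, crash_length=1,
                                n_cycles=10, amplitude=1.0)


@pytest.fixture
def gamma4():
    return FitnessParams(gamma=4.0)


@pytest.fixture
def small_abm_config():
    """A quick-to-run ABM configuration for unit tests."""
    return ABMConfig(n_agents=50, record_every=5, seed=7)


@pytest.fixture
def const_env():
    return EnvironmentSeries(np.zeros(40))
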