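import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renogfr.io_types import Aif, TwoCfmParams
from renogfr.synthetic_data import (
    AifParams,
    PhantomSpec,
    make_aif,
    make_phantom,
)

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

#: small phantom geometry used throughout the fitting tests: large enough
#: that every role is populated, small enough for seconds-scale fits
SMALL_SHAPE = (16, 12, 6)


@pytest.fixture(scope="session")
def times():
    """The nominal dynamic grid: 0.9 s frames over 7 minutes."""
    return 0.9 * np.arange(467)


@pytest.fixture(scope="session")
def aif(times):
    return make_aif(times, AifParams())


@pytest.fixture(scope="session")
def cortex_truth():
    return TwoCfmParams(F_P=180.0, V_P=22.0, F_T=68.0, T_T=120.0, delay=0.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free small phantom with its mask and ground-truth maps."""
    spec = PhantomSpec(shape=SMALL_SHAPE, n_volumes=300, noise_sigma=0.0)
    return make_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def fast_fit_config():
    """Fit options for tests where the true delay is 0: skips the delay grid."""
    return {"delay_grid": (0.0,), "n_starts": 2}


@pytest.fixture
def delta_aif():
    """Near-delta AIF of unit area on a fine grid (one-compartment limit)."""
    dt = 0.01
    t = np.arange(0.0, 120.0, dt)
    conc = np.zeros_like(t)
    conc[1] = 1.0 / dt
    return Aif(t, conc)
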