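import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eicoquant.method_library import (
    default_spectral_library,
    load_bundled_rt_table,
    load_bundled_transitions,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return load_bundled_transitions()


@pytest.fixture(scope="session")
def rt_table():
    return load_bundled_rt_table()


@pytest.fixture(scope="session")
def spectral_library(library):
    return default_spectral_library(library)


@pytest.fixture(scope="session")
def by_id(library):
    return {t.analyte_id: t for t in library}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
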