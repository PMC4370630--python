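import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reefwave.series import EnvironmentalSeries

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def series_factory():
    """Factory building a uniform EnvironmentalSeries from raw values."""

    def make(values, dt=600.0, variable="value", site="test", valid=None, start="2012-05-24"):
        return EnvironmentalSeries.from_regular(
            start, dt, np.asarray(values, dtype=float),
            site=site, variable=variable, valid=valid,
        )

    return make
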