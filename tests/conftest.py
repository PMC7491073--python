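import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def control_params():
    from tracemet.presets import control_flux_params

    return control_flux_params()


@pytest.fixture
def ftd3_params():
    from tracemet.presets import ftd3_flux_params

    return ftd3_flux_params()


@pytest.fixture
def glucose_cfg():
    from tracemet.propagate import glucose_tracer

    return glucose_tracer()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
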