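import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tissuecond as tc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def mold_sample():
    """The standard cylindrical mold: 3 mm radius, 0.56 cm thickness."""
    return tc.CylindricalSample(sample_id="s1", tissue_label="Panc01 tumor")


@pytest.fixture
def flat_sigma_model():
    """Degenerate field-independent conductivity of 0.2 S/m."""
    return tc.DynamicConductivityModel(sigma0_s_per_m=0.2, sigma_max_s_per_m=0.2)


@pytest.fixture
def sigmoid_model():
    """Default sigmoid sigma(E): 0.24 -> 0.40 S/m around 1000 V/cm."""
    return tc.DynamicConductivityModel()


def runs_from_records(records):
    return [tc.SampleRun(r.sample, r.diagnostic, r.ire, r.protocol) for r in records]


@pytest.fixture
def runs_factory():
    return runs_from_records


@pytest.fixture
def square_recording():
    """Hand-built single square pulse: 1 V / 5 mA plateau, 100 samples wide."""
    fs = 1e6
    n = 1000
    v = np.zeros(n)
    i = np.zeros(n)
    v[400:500] = 1.0
    i[400:500] = 5e-3
    return tc.PulseRecording(
        time_s=np.arange(n) / fs, voltage_v=v, current_a=i, sampling_rate_hz=fs
    )
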