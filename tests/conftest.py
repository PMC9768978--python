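import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20221220)


@pytest.fixture()
def grid16():
    from meanet.io import ElectrodeLayout

    return ElectrodeLayout.grid(4, 4, pitch_um=450.0)


@pytest.fixture()
def single_channel_layout():
    from meanet.io import ElectrodeLayout

    return ElectrodeLayout(np.array([1]), np.array([[0.0, 0.0]]))
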