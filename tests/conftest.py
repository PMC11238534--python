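import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "thermocap",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("thermocap")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ligand0_params():
    from thermocap import datasets

    return datasets.equilibrium_params("0")


@pytest.fixture
def ligand3_params():
    from thermocap import EquilibriumParams

    return EquilibriumParams(dh_eq=17.86, ds_eq=0.0601, dh_b=3.69)
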