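import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from staturekit import datasets, fit_polynomial

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def male_curve():
    return fit_polynomial(datasets.synthetic_reference_table("M"), degree=5)


@pytest.fixture(scope="session")
def female_curve():
    return fit_polynomial(datasets.synthetic_reference_table("F"), degree=5)


@pytest.fixture(scope="session")
def male_bmi_table():
    return datasets.synthetic_standard_bmi_table("M")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
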