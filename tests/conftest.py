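import pytest
from hypothesis import HealthCheck, settings

from ssir import load_antihiv, load_toy

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.large_base_example],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    return load_toy()


@pytest.fixture(scope="session")
def antihiv():
    return load_antihiv()


@pytest.fixture(scope="session")
def trn(antihiv):
    return antihiv.subset("TRN")


@pytest.fixture(scope="session")
def ex1(antihiv):
    return antihiv.subset("Ex1")


@pytest.fixture(scope="session")
def ex2(antihiv):
    return antihiv.subset("Ex2")
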