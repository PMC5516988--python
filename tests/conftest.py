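import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allobci import MorphRecord, Stratum, generate_fixture, generate_population, stratify

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_population():
    """One study-design two-sex synthetic population (114 F + 134 M)."""
    return generate_population(seed=42)


@pytest.fixture(scope="session")
def default_strata(default_population):
    return stratify(default_population, "sex")


@pytest.fixture(scope="session")
def perfect_stratum():
    """Noise-free power laws: mass ~ L^3, fat ~ L^5, log-log r2 = 1."""
    return Stratum("female", tuple(generate_fixture("perfect-power-law")))


@pytest.fixture()
def small_records():
    """Six hand-written records, two sexes."""
    return [
        MorphRecord("a", "female", 150.0, 3000.0, 200.0),
        MorphRecord("b", "female", 200.0, 7500.0, 600.0),
        MorphRecord("c", "female", 250.0, 15500.0, 1500.0),
        MorphRecord("d", "male", 140.0, 2500.0, 150.0),
        MorphRecord("e", "male", 190.0, 6200.0, 420.0),
        MorphRecord("f", "male", 240.0, 12800.0, 980.0),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
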