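import numpy as np
import pytest

from probdem import CountryReference, SimConfig, generate_cohort, generate_reference


@pytest.fixture(scope="session")
def small_reference():
    """Four countries with distinct prevalences and population sizes."""
    return generate_reference(4, (0.03, 0.08), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    """A 4-country cohort, 1500 respondents each, default generator."""
    cfg = SimConfig(countries=small_reference, n_per_country=1500, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def single_country():
    return [CountryReference("AT", 0.05, 2.0)]
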