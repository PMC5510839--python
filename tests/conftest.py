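import pytest

from obcea import (AgeProfile, AnalysisConfig, DalyParameters, datasets)


@pytest.fixture(scope="session")
def params():
    """Default discounted, age-weighted DALY constants."""
    return DalyParameters()


@pytest.fixture(scope="session")
def params_undiscounted():
    return DalyParameters().undiscounted()


@pytest.fixture(scope="session")
def profile():
    return AgeProfile()


@pytest.fixture(scope="session")
def series():
    """The packaged 2007-2011 hospital-year outcome series."""
    return datasets.load_hospital_years()


@pytest.fixture(scope="session")
def ledger():
    """The packaged program budget ledger (2015 USD)."""
    return datasets.load_budget()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()
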