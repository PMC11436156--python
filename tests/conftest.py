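import pytest

from sccspool import Registry, SccsDesign, default_registry


@pytest.fixture(scope="session")
def myocarditis_design() -> SccsDesign:
    """RI 3.0, 28-day risk window in 180 days, alpha 0.05, power 0.90."""
    return SccsDesign(relative_incidence=3.0, risk_days=28, observation_days=180)


@pytest.fixture(scope="session")
def vitt_design() -> SccsDesign:
    """RI 5.0 with the same windows, alpha, and power."""
    return SccsDesign(relative_incidence=5.0, risk_days=28, observation_days=180)


@pytest.fixture(scope="session")
def registry() -> Registry:
    return default_registry()
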