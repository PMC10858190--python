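import pytest

from icidose import (ModelParams, SimulationSettings, derive_pk_rates,
                     fractionation_sweep)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def pk():
    return derive_pk_rates()


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def dose50_sweep(params, pk, settings):
    """The cumulative-dose-50 fractionation sweep (2-12 doses x 1-10 day
    spacings) shared by the sweep-level acceptance checks."""
    return fractionation_sweep(50.0, params, pk, settings)
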