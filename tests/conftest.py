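import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soilweb as sw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def brasschaat():
    """Packaged sandy pine-forest site configuration."""
    return sw.brasschaat_config()


@pytest.fixture(scope="session")
def climate_1y():
    return sw.synthetic_climate(366, seed=42)


@pytest.fixture(scope="session")
def climate_10y():
    return sw.synthetic_climate(3653, seed=42)


@pytest.fixture()
def zero_biology(brasschaat):
    """All live pools and inputs zero: hydrology-only dynamics."""
    cfg = brasschaat.copy()
    for g in sw.GUILDS:
        cfg.initial_pools[g] = 0.0
    cfg.initial_pools["dom"] = 0.0
    from soilweb.core_state import ExternalInputs

    cfg.inputs = ExternalInputs()
    return cfg


def initial_total(config):
    """Total carbon of the configured initial pools."""
    return sum(config.initial_pools[p] for p in sw.POOLS)
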