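import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# replicate-drop / censoring warnings are expected noise in bulk simulations
logging.getLogger("cooktime.wab").setLevel(logging.ERROR)
logging.getLogger("cooktime.density").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_campaign():
    """One default 36-genotype campaign, shared across read-only tests."""
    from cooktime import generate_campaign

    return generate_campaign(seed=7)


@pytest.fixture(scope="session")
def small_campaign_wab(small_campaign):
    from cooktime import analyze_wab_campaign

    return analyze_wab_campaign(
        small_campaign.weights, small_campaign.softening, dmc=small_campaign.dmc
    )
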