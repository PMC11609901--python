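import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isoreduce as ir

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ZERO_NOISE = {"d2H": 0.0, "d13C": 0.0, "d18O": 0.0}


@pytest.fixture(scope="session")
def materials():
    return ir.default_materials()


@pytest.fixture(scope="session")
def waters():
    return ir.default_waters()


@pytest.fixture
def zero_noise():
    return dict(ZERO_NOISE)


@pytest.fixture(scope="session")
def quiet_run(materials, waters):
    """A zero-noise run with all instrument effects switched off."""
    cfg = ir.GeneratorConfig(
        seed=11,
        noise_sd=dict(ZERO_NOISE),
        memory_fraction=0.0,
        reactor_carbon_fraction=0.0,
    )
    run, truth = ir.generate_run(cfg, materials, waters)
    return run, truth
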