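import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def study_year():
    """One simulated study year at default (study-scale) settings."""
    from streamcom import default_config, generate_community

    return generate_community(default_config(seed=7))


@pytest.fixture
def separated_year():
    """A study year with five well-separated static regimes (no drift)."""
    from streamcom import RegimeSpec, SimulationConfig, generate_community

    regimes = [
        RegimeSpec(1, "2013-04-25", "2013-05-31", 0.0, 1.6),
        RegimeSpec(2, "2013-06-01", "2013-07-31", 0.0, 1.4),
        RegimeSpec(3, "2013-08-01", "2013-11-30", 0.0, 1.3),
        RegimeSpec(4, "2013-12-01", "2014-01-31", 0.0, 1.8),
        RegimeSpec(5, "2014-02-01", "2014-04-30", 0.0, 2.5),
    ]
    cfg = SimulationConfig(regimes=regimes, disjoint_supports=True, seed=11)
    return generate_community(cfg)
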