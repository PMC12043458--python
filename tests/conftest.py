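import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_records():
    """One default synthetic trial (5 sites x 5 treatments x 3 reps)."""
    from ofswheat import default_config, generate_trial

    return generate_trial(default_config(seed=1))


@pytest.fixture(scope="session")
def default_params():
    """Packaged health-model parameter set."""
    from ofswheat import load_health_params

    return load_health_params()
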