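import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def matched_params():
    """Matched-intensity reference parameter set: 1/λ = 100 ms, ω = 100 ms,
    μ = 100 ms, Δ = 20 ms."""
    from twinrt import TwinParams

    return TwinParams(lambda_v=0.01, lambda_a=0.01, omega=100.0, delta=20.0, mu=100.0)


@pytest.fixture
def figure1_params():
    """Intense-stimulus member of the figure-level family: 1/λ = 20 ms."""
    from twinrt import TwinParams

    return TwinParams(lambda_v=0.05, lambda_a=0.05, omega=100.0, delta=20.0, mu=100.0)
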