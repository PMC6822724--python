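import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def musician():
    from sappa.core import musician_params

    return musician_params(f=1.0)


@pytest.fixture(scope="session")
def nonmusician():
    from sappa.core import nonmusician_params

    return nonmusician_params(f=1.0)


@pytest.fixture(scope="session")
def driven_reference_trajectory():
    """One smooth delayed-feedback run reused by several numerical checks."""
    from sappa.core import FeedbackMode, OscillatorParams, StimulusKind, StimulusSpec
    from sappa.integrator import integrate

    params = OscillatorParams(f=1.0, D=0.36, tau=0.2, A=-0.5)
    spec = StimulusSpec(
        kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=FeedbackMode.CONSTANT_SELF
    )
    traj = integrate(params, spec, duration=5.0, dt=1e-3)
    return params, spec, traj
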