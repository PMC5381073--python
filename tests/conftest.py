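import pytest

from microlv import (
    ModelParameters,
    PopulationState,
    build_schedule,
    control_regime,
    simulate,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Reference calibrated parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def control_trajectory(params):
    """22-day control run from the standard inoculum (tenfold daily dilution)."""
    schedule = build_schedule(control_regime(), 22)
    return simulate(params, schedule, PopulationState(P=3.6e7, C=4.2e4))
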