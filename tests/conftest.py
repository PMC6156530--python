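import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from alternanslab import ModelParameters, ModelState, pace


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters.default()


@pytest.fixture(scope="session")
def prepaced_400(default_params):
    """Pre-paced quasi-stable cell at bcl 400 ms (shared across tests).

    1200 beats suffice for the slow variables of the reduced model to settle
    at this rate.
    """
    result = pace(ModelState(), default_params, 400.0, 1200, dt=0.05)
    return result.end_state, default_params


@pytest.fixture()
def prepaced_400_copy(prepaced_400):
    state, params = prepaced_400
    return dataclasses.replace(state), params
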