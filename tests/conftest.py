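import numpy as np
import pytest
from hypothesis import settings

import intentgrid as ig
from intentgrid.simulator import DICTATOR_ORDERS, simulate_participant

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return ig.build_policy_template()


@pytest.fixture(scope="session")
def policy_u1(template):
    return ig.apply_policy_uncertainty(template, 1.0)


@pytest.fixture
def example_params():
    return ig.ParticipantParams(pHI0=0.7, uHI0=1.0, pSI0=0.5, uSI0=1.0, u_pi=1.5, eta=0.3)


@pytest.fixture
def example_session(example_params):
    rng = np.random.default_rng(11)
    return simulate_participant(
        example_params, DICTATOR_ORDERS[0], rng, participant_id="P0", gpts=64
    )


@pytest.fixture
def random_params_factory():
    """Draw valid random parameter vectors from a seeded stream."""

    def _draw(rng):
        return ig.ParticipantParams(
            pHI0=rng.uniform(0.05, 0.95),
            uHI0=np.exp(rng.uniform(np.log(0.2), np.log(5.0))),
            pSI0=rng.uniform(0.05, 0.95),
            uSI0=np.exp(rng.uniform(np.log(0.2), np.log(5.0))),
            u_pi=np.exp(rng.uniform(np.log(0.3), np.log(5.0))),
            eta=rng.uniform(0.0, 1.0),
        )

    return _draw


@pytest.fixture
def random_session_factory(random_params_factory):
    """(params, session) pairs with random orders and dictator behaviour."""

    def _draw(rng):
        params = random_params_factory(rng)
        order = DICTATOR_ORDERS[rng.integers(0, 3)]
        session = simulate_participant(
            params, order, rng, participant_id="R", gpts=int(rng.integers(32, 161))
        )
        return params, session

    return _draw
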