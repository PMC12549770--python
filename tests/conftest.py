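import numpy as np
import pytest

from rlwmlba import model, task


@pytest.fixture(scope="session")
def session_design():
    return task.generate_session(seed=123)


@pytest.fixture(scope="session")
def default_params():
    return model.SubjectParameters(
        alpha=0.05, bias=0.5, phi=0.2, rho=0.8, C=3.5, eta=5.0, A=1.2, k=1.0
    )


@pytest.fixture(scope="session")
def simulated_trials(session_design, default_params):
    return model.simulate_agent(session_design, default_params, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
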