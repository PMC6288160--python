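import numpy as np
import pytest

from crossprotect import (
    ModelParams,
    PatchState,
    benign_protocol,
    default_model_params,
    harsh_protocol,
)


@pytest.fixture(scope="session")
def model():
    return default_model_params()


@pytest.fixture(scope="session")
def benign():
    return benign_protocol()


@pytest.fixture(scope="session")
def harsh():
    return harsh_protocol()


@pytest.fixture(scope="session")
def benign_phases(model):
    """The three phase states of the benign period-3 attractor (cached
    for the whole session; several analyses start from them)."""
    from crossprotect import benign_phase_states

    return benign_phase_states(model)


@pytest.fixture
def simple_params():
    """A small, numerically tame parameter set for unit arithmetic."""
    return ModelParams(
        gamma1R=0.8,
        gamma2R=1.0,
        gamma2D=2.0,
        I12=1.0,
        I21=1.0,
        K=1e5,
        Vmax=1e-3,
        Km=1.0,
        c2=1e-4,
        t_lag=1.5,
    )
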