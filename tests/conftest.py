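import numpy as np
import pytest

from balancempc.anthropometry import build_anthropometry
from balancempc.mpc import MPCConfig, closed_loop_simulate
from balancempc.platform import PlatformSpec

from _oracles import build_lagrangian_oracle

# Sweep length used for the full closed-loop runs in the suite: long enough
# for ~0.05 Hz/s ramps (transition estimates are ramp-insensitive below
# ~0.1 Hz/s) while keeping the suite runtime moderate.
SWEEP_DURATION = 120.0


@pytest.fixture(scope="session")
def model():
    return build_anthropometry()


@pytest.fixture(scope="session")
def lagrangian_oracle():
    """Independent symbolic Euler-Lagrange dynamics (sympy-derived)."""
    return build_lagrangian_oracle()


@pytest.fixture(scope="session")
def default_run(model):
    """Full chirp sweep with the default (hip-penalised) weights."""
    res = closed_loop_simulate(model, MPCConfig(), PlatformSpec(duration=SWEEP_DURATION))
    assert not res.failed, "default-weight sweep lost balance"
    return res


@pytest.fixture(scope="session")
def equal_weight_run(model):
    """Full chirp sweep with equal torque-increment weights."""
    cfg = MPCConfig(r_diag=np.array([10.0, 10.0, 10.0]))
    res = closed_loop_simulate(model, cfg, PlatformSpec(duration=SWEEP_DURATION))
    assert not res.failed, "equal-weight sweep lost balance"
    return res
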