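import numpy as np
import pytest

from burstswitch.model_core import ModelParams, get_preset


@pytest.fixture(scope="session")
def table1() -> ModelParams:
    return get_preset("ecoli_table1")


@pytest.fixture(scope="session")
def threeway() -> ModelParams:
    return get_preset("lu_threeway")


@pytest.fixture(scope="session")
def mini_toggle() -> ModelParams:
    # reduced-size switch for fast statistical tests
    return ModelParams(B=5.0, K=50.0)


@pytest.fixture(scope="session")
def frozen_rate() -> ModelParams:
    # r = 0 freezes regulation at a constant rate a = K*r0 = 4 per cycle
    return ModelParams(B=5.0, K=50.0, r=0.0, r0=4.0 / 50.0)


@pytest.fixture(scope="session")
def high_x_attractor(table1):
    from burstswitch.model_core import find_attractors

    fp = find_attractors(table1).high_x_attractor()
    return np.array([fp.x, fp.y])
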