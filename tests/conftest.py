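import numpy as np
import pytest

import hubsens as hs


@pytest.fixture(scope="session")
def patterns():
    return hs.load_patterns()


@pytest.fixture(scope="session")
def models():
    return {mid: hs.build_model(mid) for mid in hs.MODEL_IDS}


@pytest.fixture(scope="session")
def m1(models):
    return models["M1"]


@pytest.fixture(scope="session")
def m1_control(m1):
    """Small replicate ensemble at M1 reference parameters (shared, read-only)."""
    return hs.generate_control_data(m1, n_replicates=100, dt=0.01, seed=2024)


@pytest.fixture(scope="session")
def constant_signal():
    return hs.SignalPattern(id="CONST", form="constant", kon=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(17)
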