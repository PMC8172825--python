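import numpy as np
import pytest

from thermovuln import synthetic as synth


@pytest.fixture(scope="session")
def default_cfg():
    return synth.SimConfig(seed=42)


@pytest.fixture(scope="session")
def campaign(default_cfg):
    return synth.gen_field_campaign(default_cfg)


@pytest.fixture(scope="session")
def te_series(default_cfg):
    return synth.gen_te_series(default_cfg)


@pytest.fixture(scope="session")
def lab_thermal(default_cfg):
    return synth.gen_lab_thermal(default_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
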