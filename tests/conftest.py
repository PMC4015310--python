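import numpy as np
import pytest

from telosim import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_params():
    """Reference parameterisation (400 cells, 15 kb telomeres, SITS)."""
    return ModelParams(damage_mean=0.25, damage_sd=0.375)


@pytest.fixture
def fast_params():
    """Short-lived geometry for engine tests: 10x attrition and a short
    telomere span, so a full trajectory lasts a few dozen doublings."""
    return ModelParams(damage_mean=0.25, damage_sd=0.375,
                       initial_telomere=4000.0, gamma=0.015)
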