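import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def collinear_standards():
    """Noise-free acetone standards on the line 0.75*x + 0.005."""
    from tracequant.body_water import BodyWaterStandard

    return [
        BodyWaterStandard(0.00, 0.0050),
        BodyWaterStandard(0.01, 0.0125),
        BodyWaterStandard(0.02, 0.0200),
        BodyWaterStandard(0.04, 0.0350),
    ]
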