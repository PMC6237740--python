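import numpy as np
import pytest

from hydromap import BindingParameters
from hydromap.synth import DEFAULT_R0, DEFAULT_R1


@pytest.fixture
def wt_truth() -> BindingParameters:
    """WT-like generating parameters: sub-nanomolar competitor affinity."""
    return BindingParameters(
        K_probe=1e-9, K_comp=0.34e-9, r0=DEFAULT_R0, r1=DEFAULT_R1
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180913)
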