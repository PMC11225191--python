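import numpy as np
import pytest

from hgtgames import FixedRates, get_preset


@pytest.fixture
def base_rates() -> FixedRates:
    """Shared phase-map base parameterisation (A excludes B at N = 18)."""
    return FixedRates.symmetric(r_A=1.8, r_B=1.0, a=0.1, gamma=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240704)


@pytest.fixture(params=["region_I", "region_II", "region_III"])
def oscillating_preset(request):
    return get_preset(request.param)
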