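import numpy as np
import pytest

import metcovnet as mc


@pytest.fixture
def atlas5():
    return mc.synthetic_atlas(5, n_reference=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Null cohort: two exchangeable groups of 30, 10 regions."""
    cfg = mc.preset_scenario("null", n_regions=10, seed=42)
    return mc.generate_cohort(cfg)
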