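import numpy as np
import pytest

from cstperf import fixture_compartment_atlas, make_fixture_atlas
from cstperf.atlas import apply_merge_rules, default_merge_rules


@pytest.fixture(scope="session")
def raw_atlas():
    """Unmerged fixture atlas: 40 source labels (7 S + 7 T + 6 C per hemisphere)."""
    return make_fixture_atlas(32, seed=0)


@pytest.fixture(scope="session")
def merged_atlas(raw_atlas):
    """Fixture atlas merged to the 36 analysis compartments."""
    return apply_merge_rules(raw_atlas, default_merge_rules())


@pytest.fixture(scope="session")
def small_atlas():
    """Smaller merged atlas for simulation-heavy tests."""
    return fixture_compartment_atlas(24, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
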