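import numpy as np
import pytest

from abtriage.fixtures import default_fixture_spec, make_toy_complex, split_binder_target
from abtriage.scoring import EnergyParams


@pytest.fixture
def toy():
    """Default synthetic complex: 3 strong hotspots + 1 weak site."""
    cx, truth = make_toy_complex(default_fixture_spec(0))
    return cx, truth


@pytest.fixture
def toy_parts(toy):
    cx, truth = toy
    binder, target = split_binder_target(cx)
    return cx, truth, binder, target


@pytest.fixture
def params():
    return EnergyParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
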