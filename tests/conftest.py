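import numpy as np
import pytest
from hypothesis import settings

from ampbias.model import DegradationParams, retaining_rate_curve
from ampbias.simulate import SyntheticSpec, generate_dataset

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Reference degradation parameters: L=1000, a=300, b=200 bp."""
    return DegradationParams(L=1000.0, a=300.0, b=200.0)


@pytest.fixture(scope="session")
def curve1(params):
    return retaining_rate_curve(params, 1, grid_step=2.0)


@pytest.fixture(scope="session")
def curve2(params):
    return retaining_rate_curve(params, 2, grid_step=2.0)


@pytest.fixture(scope="session")
def small_dataset():
    """2,000 probe sets under the reference conditions (cycle 2)."""
    spec = SyntheticSpec(n_probe_sets=2000, seed=11)
    probes, truth = generate_dataset(spec, cycle=2)
    return spec, probes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
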