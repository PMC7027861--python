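import numpy as np
import pytest

from cellaxis import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_population():
    """20 rod cells with 2 planted spots each, shared across read-only tests."""
    meshes, truth = synthetic.make_population(20, shape="rod", seed=7)
    spots, spot_truth = synthetic.place_spots(truth, pattern="uniform", seed=8)
    return meshes, truth, spots, spot_truth
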