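import numpy as np
import pytest

from hapi3d.biovision import fit_model
from hapi3d.phantom import PhantomSpec, make_phantom, training_patches


@pytest.fixture(scope="session")
def phantom_small():
    """Compact phantom shared by the unit tests (default study parameters
    otherwise)."""
    return make_phantom(PhantomSpec(dims=(80, 60, 20), seed=0))


@pytest.fixture(scope="session")
def phantom_default():
    """Full-size default phantom (the study conditions)."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def abeta_model(phantom_small):
    patches = training_patches(phantom_small, "abeta", n_patches=12, seed=1)
    return fit_model(patches, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
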