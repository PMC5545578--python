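import numpy as np
import pytest

from hemiconn.phantom import Bundle, PhantomSpec, make_tensor_phantom, mirror_bundles


@pytest.fixture(scope="session")
def straight_phantom():
    """Single straight bundle along +x, FA 0.8 over a 0.05 background."""
    spec = PhantomSpec(
        grid_shape=(21, 11, 11), voxel_size=(2.0, 2.0, 2.0),
        bundles=(Bundle(points=((-16.0, 0.0, 0.0), (16.0, 0.0, 0.0)),
                        radius=3.0, fa=0.8),),
        background_fa=0.05)
    vol, masks = make_tensor_phantom(spec)
    return spec, vol, masks


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Bilaterally symmetric phantom: three intra-hemispheric bundles on the
    right, mirrored to the left; odd x-dimension, world-centred grid."""
    right_bundles = (
        Bundle(points=((4.0, -8.0, 0.0), (18.0, -8.0, 0.0)), radius=2.5, fa=0.8),
        Bundle(points=((4.0, 8.0, 2.0), (18.0, 8.0, 2.0)), radius=2.5, fa=0.7),
        Bundle(points=((10.0, -2.0, -4.0), (10.0, 2.0, -4.0)), radius=2.5, fa=0.75),
    )
    spec = PhantomSpec(grid_shape=(23, 13, 9), voxel_size=(2.0, 2.0, 2.0),
                       bundles=right_bundles + mirror_bundles(right_bundles),
                       background_fa=0.05)
    vol, masks = make_tensor_phantom(spec)
    return spec, vol, masks


def random_weighted_graph(rng, n, density=0.5):
    """Random symmetric weight matrix with weights in (0, 1]."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.05, 1.0, len(iu[0])) * present
    w[iu] = vals
    return w + w.T


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
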