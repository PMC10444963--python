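import numpy as np
import pytest

from emgan3d.density_io import DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_map(rng):
    def _make(shape=(10, 12, 14), voxel=1.0, origin=(0.0, 0.0, 0.0), positive=False):
        data = rng.random(shape, dtype=np.float32)
        if not positive:
            data = data - 0.25
        return DensityMap(data, origin=np.asarray(origin), voxel_size=voxel)

    return _make


@pytest.fixture
def helix_model():
    from emgan3d.synthetic_fixtures import make_toy_structure

    return make_toy_structure("helix", 10, seed=7)
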