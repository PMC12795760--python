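import numpy as np
import pytest

from axotomo.io import Volume3D
from axotomo.synthetic import SceneSpec, make_microtubule_scene, straight_mt
from axotomo.tracing import resample_centerline


@pytest.fixture(scope="session")
def noisy_mt_scene():
    """One straight 500 nm microtubule at the study noise level, seed 1."""
    spec = SceneSpec(box_shape=(512, 44, 44),
                     microtubules=[straight_mt([21.6, 21.4, 5.0], [21.6, 21.4, 505.0])],
                     noise_snr=2.0, seed=1)
    return make_microtubule_scene(spec)


@pytest.fixture(scope="session")
def noiseless_mt_scene():
    spec = SceneSpec(box_shape=(262, 44, 44),
                     microtubules=[straight_mt([21.6, 21.4, 5.0], [21.6, 21.4, 255.0])],
                     noise_snr=None, seed=2)
    return make_microtubule_scene(spec)


@pytest.fixture(scope="session")
def straight_trace():
    """Axial centerline through voxel centers (x = y = 21) for mask checks."""
    pts = np.column_stack([np.full(2, 21.0), np.full(2, 21.0), [5.0, 105.0]])
    return resample_centerline(pts, 1.0)


@pytest.fixture
def small_volume():
    rng = np.random.default_rng(0)
    return Volume3D(grid=rng.normal(size=(16, 16, 16)).astype(np.float32))
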