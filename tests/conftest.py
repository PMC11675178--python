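import numpy as np
import pytest

from eggct.phantom import PhantomParams, generate_egg, sample_params
from eggct.preprocess import make_calibration, normalize_intensity

# desk-scale phantom grid: one egg at ~2 mm in-plane resolution fits here
SMALL_GRID = (21, 37, 29)


@pytest.fixture(scope="session")
def study_calibration():
    """The acquisition geometry: 333 mm FOV, 512 matrix, 3 mm slices."""
    return make_calibration(333, 512, 3)


@pytest.fixture(scope="session")
def small_calibration():
    """Coarser in-plane resolution (~1.96 mm) for fast network tests."""
    return make_calibration(333, 170, 3)


@pytest.fixture(scope="session")
def noiseless_egg(study_calibration):
    params = PhantomParams(noise_sd=0.0, seed=42)
    ct, labels, gt = generate_egg(params, study_calibration)
    return params, ct, labels, gt


@pytest.fixture(scope="session")
def phantom_dataset(small_calibration):
    """20 varied noiseless phantoms on a common grid, normalized to [0, 255]."""
    rng = np.random.default_rng(101)
    eggs = []
    for _ in range(20):
        p = sample_params(rng, noise_sd=0.0)
        ct, labels, gt = generate_egg(p, small_calibration, grid_shape=SMALL_GRID)
        eggs.append((normalize_intensity(ct), labels, gt))
    return eggs
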