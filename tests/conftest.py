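import numpy as np
import pytest
from hypothesis import settings

from alecontrast import BrainGrid, Experiment, KernelModel
from alecontrast.synthetic_data import make_box_grid

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid16():
    """16^3 box grid at 4 mm, the small lattice used for oracle checks."""
    return make_box_grid(shape=(16, 16, 16), voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def grid24():
    """Default 24^3 synthetic analysis grid at 4 mm."""
    return make_box_grid()


@pytest.fixture(scope="session")
def kernel():
    return KernelModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_experiment(rng, grid, max_foci=8, study_id="exp"):
    """A random experiment with foci at in-mask voxel centres (no duplicates)."""
    n_foci = int(rng.integers(1, max_foci + 1))
    picks = rng.choice(grid.n_mask, size=n_foci, replace=False)
    foci = grid.voxel_to_mm(grid.mask_indices[picks])
    n_subjects = int(rng.integers(5, 50))
    return Experiment(study_id=study_id, n_subjects=n_subjects, foci=foci)
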