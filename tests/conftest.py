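import numpy as np
import pytest

from contourqa import LabelMask, SyntheticConfig, generate_dataset, validate_pair
from contourqa.model import metrics_dataframe


def cube_mask(shape=(16, 16, 16), lo=(4, 4, 4), size=4, spacing=(1.0, 1.0, 1.0),
              origin=(0.0, 0.0, 0.0)):
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0]:lo[0] + size, lo[1]:lo[1] + size, lo[2]:lo[2] + size] = True
    return LabelMask(vox, spacing, origin)


def single_voxel(shape=(9, 9, 9), at=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=bool)
    vox[at] = True
    return LabelMask(vox, spacing)


@pytest.fixture
def shifted_cube_pair():
    """4^3 cubes offset by 2 voxels along x on a 1 mm grid (overlap 32)."""
    a = cube_mask()
    b = cube_mask(lo=(4, 4, 6))
    return validate_pair(a, b)


#: small study used by classifier/CLI tests: coarser grid, 38 pairs
SMALL_CONFIG = dict(
    n_pairs_per_set={"ref_vs_verif_internal": 10, "ref_vs_verif_external": 8,
                     "acceptable_manual": 10, "unacceptable_manual": 10},
    grid_shape=(36, 48, 48), spacing=(3.0, 2.0, 2.0), seed=123,
)


@pytest.fixture(scope="session")
def small_dataset():
    pairs, manifest = generate_dataset(SyntheticConfig(**SMALL_CONFIG))
    return pairs, manifest


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    pairs, _ = small_dataset
    return metrics_dataframe(pairs)
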