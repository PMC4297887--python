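import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cispredict import CohortConfig, VoxelGrid3D


#: Reduced lattice for simulation-heavy tests (defaults stay full-size).
SMALL_LATTICE = dict(
    native_shape=(64, 64, 24), native_voxel_mm=(3.0, 3.0, 5.0),
    template_shape=(45, 54, 45), template_voxel_mm=(4.0, 4.0, 4.0),
)


@pytest.fixture
def small_config():
    return CohortConfig(n_converters=3, n_nonconverters=3, seed=7, **SMALL_LATTICE)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_mask(dims, voxels, voxel_size=(1.0, 1.0, 1.0)) -> VoxelGrid3D:
    arr = np.zeros(dims, dtype=np.uint8)
    for v in voxels:
        arr[v] = 1
    return VoxelGrid3D(arr, voxel_size)
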