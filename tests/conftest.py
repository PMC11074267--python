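import numpy as np
import pytest

from mapforge.gridio import DensityGrid
from mapforge.labeler import BackboneResidue


@pytest.fixture
def random_grid():
    rng = np.random.default_rng(42)
    return DensityGrid(
        data=rng.random((12, 10, 8)).astype(np.float32),
        voxel_size=(0.8, 0.9, 1.1),
        origin=(-3.0, 2.5, 7.0),
    )


@pytest.fixture
def tiny_structure():
    """Three residues with all backbone atoms, on well-separated voxels."""
    return [
        BackboneResidue("A", 1, 1, ca_xyz=(2.0, 2.0, 2.0),
                        n_xyz=(1.0, 2.0, 2.0), c_xyz=(3.0, 2.0, 2.0),
                        ss_code=2),
        BackboneResidue("A", 2, 8, ca_xyz=(5.0, 3.0, 2.0),
                        n_xyz=(4.0, 3.0, 2.0), c_xyz=(6.0, 3.0, 2.0),
                        ss_code=1),
        BackboneResidue("A", 3, 20, ca_xyz=(8.0, 4.0, 3.0),
                        n_xyz=(7.0, 4.0, 3.0), c_xyz=(9.0, 4.0, 3.0),
                        ss_code=3),
    ]


@pytest.fixture
def unit_grid():
    """1 A voxel grid, origin 0, large enough for tiny_structure."""
    return DensityGrid(data=np.zeros((12, 12, 12), dtype=np.float32))
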