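import numpy as np
import pytest

from flycount3d import StackRecipe, VoxelGrid, make_cell_stack


def grid_1d(values, **kw):
    """Embed a 1-D intensity profile as a (1,1,n) VoxelGrid."""
    data = np.asarray(values, dtype=np.uint8).reshape(1, 1, -1)
    return VoxelGrid(data, **kw)


@pytest.fixture(scope="session")
def clean_stack_20():
    """20 non-touching somata, noise-free, with ground truth."""
    recipe = StackRecipe(n_cells=20, touching_fraction=0.0, noise="none", rng_seed=11)
    return make_cell_stack(recipe)


@pytest.fixture(scope="session")
def noisy_stack_20():
    """20 non-touching somata with Poisson noise."""
    recipe = StackRecipe(n_cells=20, touching_fraction=0.0, noise="poisson", rng_seed=12)
    return make_cell_stack(recipe)
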