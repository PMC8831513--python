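import numpy as np
import pytest

from abscesspdt import (
    DoseTargets,
    LabelGrid,
    PhantomSpec,
    generate_phantom,
    wall_surface,
)


@pytest.fixture(scope="session")
def small_sphere_grid():
    """Sphere cavity r = 1 cm, 0.1 cm voxels, 0.2 cm wall, 1 cm pad."""
    return generate_phantom(PhantomSpec(shape="sphere", radius=1.0, spacing=(0.1, 0.1, 0.1)))


@pytest.fixture(scope="session")
def small_sphere_surface(small_sphere_grid):
    return wall_surface(small_sphere_grid)


@pytest.fixture(scope="session")
def homogeneous_grid_64():
    """64^3 single-region grid, 0.05 cm voxels (3.2 cm cube), label 2."""
    labels = np.full((64, 64, 64), 2, dtype=np.int8)
    return LabelGrid(labels, (0.05, 0.05, 0.05))


@pytest.fixture(scope="session")
def targets():
    return DoseTargets()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
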