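import numpy as np
import pytest

from vasculograph import (
    PhantomSpec,
    SkeletonVolume,
    generate_tree,
    rasterize,
)


@pytest.fixture(scope="session")
def tree3_spec() -> PhantomSpec:
    """Depth-3 full binary tree in a grid roomy enough that nothing clips."""
    return PhantomSpec(n_levels=3, grid_shape=(128, 128, 128), seed=2)


@pytest.fixture(scope="session")
def tree3(tree3_spec):
    return generate_tree(tree3_spec)


@pytest.fixture(scope="session")
def tree3_raster(tree3, tree3_spec):
    volume, mask = rasterize(tree3, tree3_spec)
    return volume, mask


@pytest.fixture
def line_skeleton() -> SkeletonVolume:
    """Straight 10-voxel axis-aligned line."""
    v = np.zeros((5, 5, 16), dtype=bool)
    v[2, 2, 3:13] = True
    return SkeletonVolume(v, 4.5)


@pytest.fixture
def y_skeleton() -> SkeletonVolume:
    """Three straight arms meeting at one center voxel."""
    v = np.zeros((9, 9, 9), dtype=bool)
    for i in range(5):
        v[4, 4, i] = True  # stem
    for i in range(1, 4):
        v[4, 4 + i, 4 + i] = True
        v[4, 4 - i, 4 + i] = True
    return SkeletonVolume(v, 4.5)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
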