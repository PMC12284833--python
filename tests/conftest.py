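import numpy as np
import pytest

from lungparc.grid import ImageGrid
from lungparc.phantom import PhantomSpec, generate
from lungparc.taxonomy import build_taxonomy


@pytest.fixture(scope="session")
def tax():
    return build_taxonomy()


@pytest.fixture(scope="session")
def bundle48():
    """Small phantom shared across tests (48 mm cube at 1 mm)."""
    return generate(PhantomSpec(seed=5, grid=ImageGrid((48, 48, 48))))


@pytest.fixture(scope="session")
def bundle96():
    """Default-size phantom (96 mm cube at 1 mm)."""
    return generate(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def bundle96b():
    """Second default-size phantom with an independent seed."""
    return generate(PhantomSpec(seed=7))


def tree_root_voxel(bundle):
    """Seed voxel for tracing: the tree root's voxel."""
    root = bundle.tree.nodes[bundle.tree.root_id]
    return tuple(
        int(i) for i in bundle.prob.grid.round_to_voxel(np.array(root.position))
    )
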