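import numpy as np
import pytest

from persfp.fixtures import make_k22_generic, make_pair, make_square
from persfp.structures import ElementPairSubset, LabeledPointCloud


@pytest.fixture
def square():
    return make_square(9.75)


@pytest.fixture
def pair():
    return make_pair(5.0)


@pytest.fixture
def k22():
    return make_k22_generic()


def random_cloud(p: int, q: int, seed: int, box: float = 12.0) -> LabeledPointCloud:
    """A bare labeled point cloud (no ComplexStructure) for persistence tests."""
    rng = np.random.default_rng(seed)
    pro = rng.uniform(0, box, size=(p, 3))
    lig = rng.uniform(0, box, size=(q, 3))
    return LabeledPointCloud(
        [(f"P{i}", tuple(map(float, x))) for i, x in enumerate(pro)],
        [(f"L{j}", tuple(map(float, x))) for j, x in enumerate(lig)],
        ElementPairSubset("C", "C"),
    )


def random_rotation(seed: int) -> np.ndarray:
    """A uniform random rotation matrix via QR of a Gaussian matrix."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
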