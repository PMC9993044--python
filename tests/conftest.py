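import numpy as np
import pytest

from kinetomt import (
    FixtureSpec,
    LatticeParams,
    build_straight_mt,
    make_dash_protomer,
    make_ndc80c_rod,
    make_pseudo_tubulin,
    make_toy_interface,
)


@pytest.fixture(scope="session")
def tubulin():
    return make_pseudo_tubulin(FixtureSpec("pseudo_tubulin"))


@pytest.fixture(scope="session")
def params():
    return LatticeParams()


@pytest.fixture(scope="session")
def straight_mt(tubulin, params):
    return build_straight_mt(tubulin, params, 3)


@pytest.fixture()
def rod():
    return make_ndc80c_rod(FixtureSpec("ndc80c_rod"))


@pytest.fixture(scope="session")
def protomer():
    return make_dash_protomer(FixtureSpec("dash_protomer"))


@pytest.fixture(scope="session")
def toy_interface():
    return make_toy_interface(FixtureSpec("toy_interface"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    from kinetomt.geometry import RigidTransform

    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(R, rng.uniform(-50, 50, size=3))
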