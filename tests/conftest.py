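import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molscene import (
    RigidTransform,
    Scene,
    SceneObject,
    make_fixture,
)

try:  # hypothesis settings are applied only if the plugin is importable
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def random_transform(rng: np.random.Generator, span: float = 10.0) -> RigidTransform:
    """Uniform random rotation (Haar measure) + uniform translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-span, span, 3))


@pytest.fixture(scope="session")
def coarse_sphere():
    """80-face unit icosphere used throughout collision tests."""
    return make_fixture("sphere", {"radius": 1.0, "subdivisions": 1})


@pytest.fixture(scope="session")
def fine_sphere():
    return make_fixture("sphere", {"radius": 1.0, "subdivisions": 3})


@pytest.fixture()
def wall_scene():
    """A unit sphere hovering over a broad slab whose top face is y = 0."""
    sc = Scene()
    sc.add_object(
        SceneObject(
            "ball",
            make_fixture("sphere", {"radius": 1.0, "subdivisions": 2}),
            RigidTransform.from_translation([0.0, 3.0, 0.0]),
        )
    )
    sc.add_object(
        SceneObject(
            "wall",
            make_fixture("box", {"extents": [24.0, 1.0, 24.0], "center": [0.0, -0.5, 0.0]}),
        )
    )
    return sc


@pytest.fixture(scope="session")
def tripeptide_path():
    import pathlib

    return pathlib.Path(__file__).parent / "data" / "tripeptide.pdb"


@pytest.fixture(scope="session")
def twochain_path():
    import pathlib

    return pathlib.Path(__file__).parent / "data" / "twochain.pdb"
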