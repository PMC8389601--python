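import pytest

from eggmech import EggGeometry, Material


@pytest.fixture(scope="session")
def material():
    return Material()


@pytest.fixture(scope="session")
def elephant_bird_geometry():
    """Aepyornis maximus egg: the largest known, 303 x 224 mm, 3.7 mm shell."""
    return EggGeometry(303.0, 224.0, 3.7)


@pytest.fixture(scope="session")
def rhea_geometry():
    """Greater rhea egg, 128 x 86 mm, 0.90 mm shell."""
    return EggGeometry(128.0, 86.0, 0.90)


@pytest.fixture(scope="session")
def sphere_geometry():
    """Spherical shell, 100 mm diameter, 1 mm wall."""
    return EggGeometry(100.0, 100.0, 1.0)
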