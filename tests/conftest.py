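import numpy as np
import pytest

from seedsynth import sprites
from seedsynth.morpho import Contour


@pytest.fixture(scope="session")
def small_pool():
    """A small deterministic sprite pool for composition tests."""
    return sprites.make_fixture_pool(rng_seed=1, n_cultivars=3, per_cultivar=3, n_backgrounds=2)


@pytest.fixture(scope="session")
def disc_mask():
    yy, xx = np.mgrid[0:220, 0:220]
    return (xx - 110) ** 2 + (yy - 110) ** 2 <= 100**2


@pytest.fixture(scope="session")
def ellipse_mask():
    """Axis-aligned filled ellipse with semi-axes (60, 30)."""
    yy, xx = np.mgrid[0:160, 0:260]
    return ((xx - 130) / 60.0) ** 2 + ((yy - 80) / 30.0) ** 2 <= 1.0


def polygon_circle(r=50.0, n=400, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)]))


def polygon_ellipse(a=60.0, b=30.0, n=400):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))


@pytest.fixture(scope="session")
def circle_contour():
    return polygon_circle()


@pytest.fixture(scope="session")
def ellipse_contour():
    return polygon_ellipse()
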