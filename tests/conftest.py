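import numpy as np
import pytest

from dsadetect.core_types import View
from dsadetect.synthetic_dsa import (
    Curve,
    SyntheticScene,
    generate_scene,
    render_views,
)


def straight_tube(x: float = 0.5, y: float = 0.5, radius: float = 0.025) -> Curve:
    """A straight vertical tube (constant radius) spanning most of the cube."""
    n = 400
    t = np.linspace(0.0, 1.0, n)
    pts = np.column_stack([np.full(n, x), np.full(n, y), 0.1 + 0.8 * t])
    return Curve(points=pts, radii=np.full(n, radius))


def horizontal_tube(y: float = 0.7, z: float = 0.5, radius: float = 0.025) -> Curve:
    n = 400
    t = np.linspace(0.0, 1.0, n)
    pts = np.column_stack([0.1 + 0.8 * t, np.full(n, y), np.full(n, z)])
    return Curve(points=pts, radii=np.full(n, radius))


@pytest.fixture(scope="session")
def tube_scene():
    return SyntheticScene(curves=[straight_tube()], aneurysms=[], noise_sd=0.0)


@pytest.fixture(scope="session")
def crossing_scene():
    """Two tubes that cross in the frontal projection but not in 3D."""
    return SyntheticScene(
        curves=[straight_tube(y=0.3), horizontal_tube(y=0.7)],
        aneurysms=[],
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def pos_scene():
    """Noise-free 3-vessel scene with one aneurysm."""
    return generate_scene(3, 1, seed=42, noise_sd=0.0)


@pytest.fixture(scope="session")
def pos_views(pos_scene):
    return render_views(pos_scene)


@pytest.fixture(scope="session")
def neg_scene():
    """Noise-free 3-vessel scene with no aneurysm (crossings present)."""
    return generate_scene(3, 0, seed=42, noise_sd=0.0)


@pytest.fixture(scope="session")
def neg_views(neg_scene):
    return render_views(neg_scene)
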