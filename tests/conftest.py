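import numpy as np
import pytest

from reefc import Contour, HeightGrid
from reefc.surfaces import as_model, plane


def make_contour(points) -> Contour:
    """Wrap an analytic polyline as a Contour (cut assumed along +X)."""
    pts = np.asarray(points, float)
    return Contour(pts, origin=pts[0, :2].copy(),
                   direction=np.array([1.0, 0.0]))


def make_grid(heights, spacing: float = 0.1) -> HeightGrid:
    """HeightGrid from a raw height array (origin at 0,0)."""
    h = np.asarray(heights, float)
    ny, nx = h.shape
    xs = spacing * np.arange(nx)
    ys = spacing * np.arange(ny)
    return HeightGrid(spacing, xs, ys, h,
                      (0.0, 0.0, xs[-1], ys[-1]))


@pytest.fixture(scope="session")
def flat_model():
    """2 x 2 m flat quadrat at z = 0 (session-cached: read-only)."""
    mesh, _ = plane(side=2.0, mesh_step=0.02)
    return as_model(mesh)


@pytest.fixture
def rng():
    return np.random.default_rng(20170413)
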