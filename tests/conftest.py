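import numpy as np
import pytest

from craniocurve.curvature import mean_curvature
from craniocurve.features import features_from_mesh
from craniocurve.mesh_io import snap_landmarks
from craniocurve.synthetic import HeadParams, make_fixture, make_head


@pytest.fixture(scope="session")
def sphere100():
    """Icosphere, radius 100 mm, analytic H = +10 m^-1."""
    return make_fixture("sphere", 100.0, resolution=4)


@pytest.fixture(scope="session")
def cylinder50():
    """Open cylinder, radius 50 mm, interior H = +10 m^-1."""
    return make_fixture("cylinder", 50.0, resolution=4)


@pytest.fixture(scope="session")
def plane_fixture():
    """Flat triangulated grid, H = 0."""
    return make_fixture("plane", 100.0, resolution=4)


@pytest.fixture(scope="session")
def sphere_field(sphere100):
    return mean_curvature(sphere100.mesh)


@pytest.fixture(scope="session")
def smooth_head():
    """Moderate-ridge head with snapped landmarks (shared, read-only)."""
    head = make_head(HeadParams(ridge_sharpness=0.5, orb_retrusion=0.3, mesh_resolution=6))
    lm = snap_landmarks(head.landmarks, head.mesh)
    return head, lm


@pytest.fixture(scope="session")
def head_features(smooth_head):
    head, lm = smooth_head
    return features_from_mesh("head", head.mesh, lm)


def sphere_landmarks_antipodal(radius=100.0):
    """Antipodal 'glabella/fontanelle' plus small rim arcs on a sphere."""
    from craniocurve.mesh_io import LandmarkSet

    theta = np.linspace(-0.3, 0.3, 5)
    rim = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros_like(theta)]
    )
    flip = rim * np.array([-1.0, 1.0, 1.0])
    return LandmarkSet(
        glabella=[0.0, 0.0, -radius],
        anterior_fontanelle=[0.0, 0.0, radius],
        rim_left=rim,
        rim_right=flip,
    )
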